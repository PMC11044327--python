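"""Epoch division, baseline-normalised summaries, cohort stacking, pipeline."""

import numpy as np
import pandas as pd
import pytest

import eitsbt as e
from eitsbt import trend_analysis as ta
from eitsbt.io_core import SBTAnnotation
from eitsbt.parameters import _PARAM_FIELDS
from eitsbt.preprocessing import ArtifactReport, Breath, StablePeriod


def _period(dzs, durations, fs=50.2, start_t=0.0):
    breaths, i = [], int(start_t * fs)
    for dz, dur in zip(dzs, durations):
        n = int(round(dur * fs))
        breaths.append(Breath(i_exp_start=i, i_insp_peak=i + n // 2, i_exp_end=i + n,
                              eeli=40.0, dz=dz, duration_s=dur))
        i += n
    return StablePeriod(i_start=breaths[0].i_exp_start, i_end=breaths[-1].i_exp_end,
                        breaths=breaths, cv_dz=0.0, cv_duration=0.0,
                        artifact_fraction=0.0)


class TestDivideEpochs:
    def test_thirty_minute_sbt_gives_six_minute_epochs(self):
        ann = SBTAnnotation(0.0, 600.0, 600.0 + 1800.0, 3000.0)
        asg = ta.divide_epochs(ann, [], fs=50.2)
        sbt_edges = [asg.edges[f"sbt_{k}"] for k in range(1, 6)]
        for lo, hi in sbt_edges:
            assert hi - lo == pytest.approx(360.0)  # 6 min

    def test_fifteen_minute_sbt_gives_three_minute_epochs(self):
        ann = SBTAnnotation(0.0, 600.0, 600.0 + 900.0, 2000.0)
        asg = ta.divide_epochs(ann, [], fs=50.2)
        for k in range(1, 6):
            lo, hi = asg.edges[f"sbt_{k}"]
            assert hi - lo == pytest.approx(180.0)

    def test_partition_is_disjoint_and_covers_sbt(self):
        ann = SBTAnnotation(0.0, 123.4, 456.7, 500.0)
        asg = ta.divide_epochs(ann, [], fs=50.2)
        edges = [asg.edges[f"sbt_{k}"] for k in range(1, 6)]
        assert edges[0][0] == ann.t_sbt_start
        assert edges[-1][1] == ann.t_sbt_end
        for (_, hi), (lo, _) in zip(edges, edges[1:]):
            assert hi == lo  # contiguous, half-open -> disjoint

    def test_boundary_breath_goes_to_later_interval(self):
        fs = 50.0
        ann = SBTAnnotation(0.0, 0.0 + 10.0, 10.0 + 50.0, 80.0)
        # breath starting exactly at the sbt_2 boundary (t = 20 s)
        p = _period([4.0] * 6, [4.0] * 6, fs=fs, start_t=20.0)
        asg = ta.divide_epochs(ann, [p], fs=fs)
        assert asg.breaths["sbt_2"][0].i_exp_start == int(20.0 * fs)
        assert not asg.breaths["sbt_1"]

    def test_every_stable_sbt_breath_assigned_exactly_once(self, recovery_session):
        res, ann = recovery_session["result"], recovery_session["ann"]
        ep = res.epochs
        n_sbt = ep.loc[ep["phase"].str.startswith("sbt"), "n_breaths"].sum()
        in_sbt = res.breaths[(res.breaths["t_start"] >= ann.t_sbt_start)
                             & (res.breaths["t_start"] < ann.t_sbt_end)]
        assert n_sbt == len(in_sbt)

    def test_count_mode_balances_breaths(self):
        ann = SBTAnnotation(0.0, 10.0, 110.0, 150.0)
        p = _period([4.0] * 23, [4.0] * 23, start_t=12.0)
        asg = ta.divide_epochs(ann, [p], fs=50.2, mode="count")
        sizes = [len(asg.breaths[f"sbt_{k}"]) for k in range(1, 6)]
        assert sum(sizes) == 23
        assert max(sizes) - min(sizes) <= 1

    def test_degenerate_sbt_window_errors(self):
        ann = SBTAnnotation(0.0, 10.0, 20.0, 30.0)
        ann.t_sbt_end = 10.0  # bypass constructor check to hit the guard
        with pytest.raises(ValueError, match="after"):
            ta.divide_epochs(ann, [], fs=50.2)


def _params_df(times, eeli=40.0, dz=4.0):
    rows = []
    for t in times:
        row = {p: np.nan for p in _PARAM_FIELDS}
        row.update(eeli=eeli, dz=dz, rr=15.0, t_start=t)
        rows.append(row)
    return pd.DataFrame(rows)


class TestSummarizeEpochs:
    def _assignment(self):
        ann = SBTAnnotation(0.0, 60.0, 360.0, 420.0)
        return ta.divide_epochs(ann, [], fs=50.2)

    def test_identical_epochs_have_zero_percent_change(self):
        df = _params_df(np.arange(5.0, 415.0, 10.0))
        out = ta.summarize_epochs(self._assignment(), df)
        assert np.allclose(out["pct_change_eeli"], 0.0)
        assert np.allclose(out["pct_change_dz"], 0.0)
        assert out.loc[out["phase"] == "pre", "pct_change_eeli"].item() == 0.0

    def test_eeli_step_reported_as_minus_twenty(self):
        t = np.arange(5.0, 415.0, 10.0)
        df = _params_df(t)
        df.loc[df["t_start"] >= 60.0, "eeli"] = 32.0  # -20% during and after
        out = ta.summarize_epochs(self._assignment(), df).set_index("phase")
        for k in range(1, 6):
            assert out.loc[f"sbt_{k}", "pct_change_eeli"] == pytest.approx(-20.0)

    def test_post_dz_restored_eeli_not(self):
        t = np.arange(5.0, 415.0, 10.0)
        df = _params_df(t)
        sbt = (df["t_start"] >= 60.0) & (df["t_start"] < 360.0)
        post = df["t_start"] >= 360.0
        df.loc[sbt, ["eeli", "dz"]] = [32.0, 3.4]
        df.loc[post, ["eeli", "dz"]] = [36.0, 4.0]
        out = ta.summarize_epochs(self._assignment(), df).set_index("phase")
        assert out.loc["post", "pct_change_dz"] == pytest.approx(0.0)
        assert out.loc["post", "pct_change_eeli"] == pytest.approx(-10.0)

    def test_empty_pre_epoch_is_an_error(self):
        df = _params_df(np.arange(65.0, 415.0, 10.0))  # nothing before 60 s
        with pytest.raises(ValueError, match="baseline"):
            ta.summarize_epochs(self._assignment(), df)

    def test_negative_baseline_keeps_sign_semantics(self):
        df = _params_df(np.arange(5.0, 415.0, 10.0), eeli=-40.0)
        df.loc[df["t_start"] >= 60.0, "eeli"] = -48.0  # further decrease
        out = ta.summarize_epochs(self._assignment(), df).set_index("phase")
        assert out.loc["sbt_3", "pct_change_eeli"] == pytest.approx(-20.0)


class TestCohort:
    def _session(self, pid, outcome, eeli=40.0):
        ann = SBTAnnotation(0.0, 60.0, 360.0, 420.0)
        asg = ta.divide_epochs(ann, [], fs=50.2)
        df = _params_df(np.arange(5.0, 415.0, 10.0), eeli=eeli)
        epochs = ta.summarize_epochs(asg, df)
        return ta.SessionResult(patient_id=pid, outcome=outcome, epochs=epochs,
                                calibration=None, breaths=df,
                                periods=pd.DataFrame(), qc=ArtifactReport())

    def test_row_count_two_sessions(self):
        params12 = _PARAM_FIELDS[:12]
        values, means = ta.cohort_table(
            [self._session("p1", "success"), self._session("p2", "failure")],
            parameters_=params12,
        )
        assert len(values) == 2 * 7 * 12  # sessions x phases x parameters

    def test_single_session_group_means_equal_values(self):
        values, means = ta.cohort_table([self._session("p1", "success")])
        merged = values.merge(means, on=["outcome", "phase", "parameter"])
        ok = merged.dropna(subset=["value"])
        np.testing.assert_allclose(ok["value"], ok["group_mean"])

    def test_missing_epochs_flagged_not_dropped(self):
        s = self._session("p1", "success")
        s.epochs.loc[s.epochs["phase"] == "sbt_2", "gi_mean"] = np.nan
        values, _ = ta.cohort_table([s], parameters_=["gi"])
        row = values[(values["phase"] == "sbt_2") & (values["parameter"] == "gi")]
        assert len(row) == 1 and bool(row["missing"].item())

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ta.cohort_table([])


class TestRunPipeline:
    def test_demo_session_writes_seven_phase_epochs(self, recovery_session):
        outdir = recovery_session["outdir"]
        for name in ("breaths.csv", "periods.csv", "epochs.csv", "qc_report.csv",
                     "session.log"):
            assert (outdir / name).exists()
        epochs = pd.read_csv(outdir / "epochs.csv")
        assert list(epochs["phase"]) == list(ta.PHASES)

    def test_missing_session_file_names_io_stage(self, tmp_path):
        cfg = ta.RunConfig(session=str(tmp_path / "nope.h5"), outdir=str(tmp_path))
        with pytest.raises(ta.PipelineError, match=r"\[io\]"):
            ta.run_pipeline(cfg, write=False)

    def test_unknown_config_key_lists_valid_keys(self):
        with pytest.raises(ValueError, match="valid keys"):
            ta.RunConfig.from_dict({"sessoin": "x.h5"})

    def test_outcome_propagated_from_annotation(self, recovery_session):
        assert recovery_session["result"].outcome == "unknown"
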