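"""Shared fixtures: small synthetic sessions generated once per run."""

import numpy as np
import pytest

import eitsbt as e


@pytest.fixture(scope="session")
def clean_minute():
    """60 s of noiseless uniform tidal breathing at 15/min (single phase)."""
    cfg = e.ScenarioConfig(
        noise_sd=0.0, cardiac_amp=0.0, spike_rate=0.0, gamma=0.0,
        phases=(e.PhaseSpec("pre", 60.0),),
    )
    return e.generate_scenario(cfg)


@pytest.fixture(scope="session")
def inhomogeneous_minute():
    """60 s noiseless sequence with an inhomogeneous amplitude map."""
    cfg = e.ScenarioConfig(
        noise_sd=0.0, cardiac_amp=0.0, spike_rate=0.0, gamma=1.0,
        phases=(e.PhaseSpec("pre", 60.0),), seed=5,
    )
    return e.generate_scenario(cfg)


@pytest.fixture(scope="session")
def recovery_session(tmp_path_factory):
    """The reference SBT scenario run end-to-end through the pipeline."""
    from eitsbt import trend_analysis as ta

    cfg = e.sbt_recovery_scenario(seed=11)
    seq, mask, vent, ann, truth = e.generate_scenario(cfg)
    d = tmp_path_factory.mktemp("recovery")
    path = d / "session.h5"
    e.write_session_container(path, seq, mask, vent, ann)
    res = ta.run_pipeline(ta.RunConfig(session=str(path), outdir=str(d / "out")))
    return dict(cfg=cfg, seq=seq, mask=mask, vent=vent, ann=ann, truth=truth,
                result=res, outdir=d / "out", session_path=path)


def matched_truth(result, truth, fs=50.2):
    """For each analyzed stable breath, the ground-truth values of its twin
    (matched by nearest true breath start frame)."""
    import pandas as pd

    ti = truth.breaths["i_start"].to_numpy()
    rows = []
    for _, b in result.breaths.iterrows():
        i_start = int(round(b["t_start"] * fs))
        r = truth.breaths.iloc[int(np.argmin(np.abs(ti - i_start)))]
        rows.append(dict(t_start=b["t_start"], eeli=r["eeli"], dz=r["dz"], rr=r["rr"]))
    return pd.DataFrame(rows)
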