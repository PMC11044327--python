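"""Per-breath EIT parameters: tidal images, GI, CoV, silent spaces,
volume calibration, RSBI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eitsbt as e
from eitsbt.io_core import LungMask, VentilatorLog
from eitsbt.parameters import (
    TidalImage,
    breath_parameters,
    calibrate_volume,
    compute_cov,
    compute_gi,
    compute_silent_spaces,
    tidal_image,
)
from eitsbt.preprocessing import Breath, global_signal, segment_breaths


def _ti(values, mask=None):
    """TidalImage from a flat row of lung values."""
    arr = np.asarray(values, dtype=float)[None, :]
    m = np.ones_like(arr, dtype=int) if mask is None else np.asarray(mask)[None, :]
    return TidalImage(di=arr, mask=LungMask(mask=m))


def _grid_ti(di, mask):
    return TidalImage(di=np.asarray(di, dtype=float), mask=LungMask(mask=np.asarray(mask)))


class TestGI:
    def test_uniform_image_is_exactly_zero(self):
        assert compute_gi(_ti([2.5] * 9)) == 0.0

    def test_hand_values(self):
        assert compute_gi(_ti([1.0, 2.0, 3.0])) == pytest.approx(1 / 3, abs=1e-15)
        assert compute_gi(_ti([0.0, 0.0, 10.0, 10.0])) == pytest.approx(1.0, abs=1e-15)

    def test_nonpositive_sum_flagged_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = compute_gi(_ti([-1.0, -2.0, 1.0]))
        assert np.isnan(out)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 1e6))
    def test_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(2.0, 1.0, size=40) + 1e-6
        assert compute_gi(_ti(k * vals)) == pytest.approx(compute_gi(_ti(vals)), rel=1e-9)

    def test_matches_generator_oracle_on_noiseless_breath(self, inhomogeneous_minute):
        seq, mask, _, _, truth = inhomogeneous_minute
        breaths = segment_breaths(global_signal(seq, mask))
        ti = tidal_image(seq, breaths[3], mask)
        gi_oracle = e.true_gi_of_map(truth.amplitude_maps["pre"], mask)
        assert compute_gi(ti) == pytest.approx(gi_oracle, rel=1e-12)


class TestTidalImage:
    def test_equals_amplitude_map_noiseless(self, inhomogeneous_minute):
        seq, mask, _, _, truth = inhomogeneous_minute
        breaths = segment_breaths(global_signal(seq, mask))
        ti = tidal_image(seq, breaths[2], mask)
        amp = truth.amplitude_maps["pre"]
        scale = ti.lung_values.sum() / amp[mask.mask].sum()
        np.testing.assert_allclose(ti.lung_values, scale * amp[mask.mask], rtol=0.01)

    def test_sum_equals_global_dz(self, inhomogeneous_minute):
        seq, mask, *_ = inhomogeneous_minute
        gs = global_signal(seq, mask)
        breaths = segment_breaths(gs)
        b = breaths[1]
        ti = tidal_image(seq, b, mask)
        dz_global = gs.z[b.i_insp_peak] - gs.z[b.i_exp_start]
        assert abs(ti.lung_values.sum() - dz_global) / dz_global < 1e-9

    def test_breath_outside_sequence_errors(self, clean_minute):
        seq, mask, *_ = clean_minute
        bad = Breath(i_exp_start=seq.n_frames - 2, i_insp_peak=seq.n_frames + 5,
                     i_exp_end=seq.n_frames + 9, eeli=1.0, dz=1.0, duration_s=2.0)
        with pytest.raises(ValueError, match="outside"):
            tidal_image(seq, bad, mask)


class TestCoV:
    def test_symmetric_map_is_centred(self):
        di = np.ones((5, 5))
        assert compute_cov(_grid_ti(di, np.ones((5, 5), dtype=int))) == (50.0, 50.0)

    def test_all_weight_in_most_dorsal_row(self):
        di = np.zeros((4, 3))
        di[3, :] = 1.0
        cov_x, cov_y = compute_cov(_grid_ti(di, np.ones((4, 3), dtype=int)))
        assert cov_y == 100.0

    def test_two_pixels_at_bounding_rows_average(self):
        di = np.zeros((7, 3))
        di[0, 1] = 1.0
        di[6, 1] = 1.0
        _, cov_y = compute_cov(_grid_ti(di, np.ones((7, 3), dtype=int)))
        assert cov_y == pytest.approx(50.0)

    def test_no_positive_weight_is_missing(self):
        with pytest.warns(UserWarning, match="CoV"):
            cov_x, cov_y = compute_cov(_ti([-1.0, -2.0]))
        assert np.isnan(cov_x) and np.isnan(cov_y)


class TestSilentSpaces:
    def test_hand_example_half_silent(self):
        nss, dss, fls = compute_silent_spaces(_ti([10.0, 5.0, 0.5, 0.9]))
        assert fls == 50.0  # threshold 1.0 -> two silent pixels of four

    def test_uniform_positive_map_fully_functional(self):
        nss, dss, fls = compute_silent_spaces(_ti([3.0] * 8))
        assert (nss, dss, fls) == (0.0, 0.0, 100.0)

    def test_no_ventilation_all_silent_with_warning(self):
        with pytest.warns(UserWarning, match="no ventilated"):
            nss, dss, fls = compute_silent_spaces(_ti([0.0, -1.0, 0.0]))
        assert fls == 0.0
        assert nss + dss + fls == 100.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_sums_to_exactly_100(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(2, 12), rng.integers(2, 12))
        mask = rng.random(shape) < 0.6
        if not mask.any():
            mask[0, 0] = True
        di = rng.normal(1.0, 1.0, shape)
        ti = TidalImage(di=di, mask=LungMask(mask=mask.astype(int)))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nss, dss, fls = compute_silent_spaces(ti)
        assert nss + dss + fls == 100.0

    def test_dependent_means_dorsal(self):
        # silent pixel in the most dorsal row, ventilation ventral
        di = np.zeros((6, 2))
        di[0:3, :] = 5.0
        di[5, 0] = 0.01
        mask = np.zeros((6, 2), dtype=int)
        mask[0:3, :] = 1
        mask[5, 0] = 1
        nss, dss, fls = compute_silent_spaces(_grid_ti(di, mask))
        assert dss > 0 and nss == 0.0


class TestCalibration:
    def _breath(self, i0, dz, fs=50.0, dur=4.0):
        n = int(dur * fs)
        return Breath(i_exp_start=i0, i_insp_peak=i0 + n // 2, i_exp_end=i0 + n,
                      eeli=10.0, dz=dz, duration_s=dur)

    def test_single_point_division(self):
        vent = VentilatorLog(timestamps=np.arange(10.0), tidal_volume=np.full(10, 400.0))
        cal = calibrate_volume([self._breath(0, 8.0)], vent, fs=50.0,
                               method="single_point")
        assert cal.c == 50.0
        assert cal.method == "single_point"

    def test_mean_of_points(self):
        breaths = [self._breath(0, 8.0), self._breath(250, 8.0), self._breath(500, 50.0 / 7.0)]
        vt = np.full(20, 400.0)
        vent = VentilatorLog(timestamps=np.arange(20.0), tidal_volume=vt)
        cal = calibrate_volume(breaths, vent, fs=50.0)
        # points are 50, 50 and 56 ml/AU -> mean 52
        assert cal.c == pytest.approx(52.0)
        assert cal.n_points == 3

    def test_recovers_true_constant_from_synthetic(self, recovery_session):
        res = recovery_session["result"]
        truth = recovery_session["truth"]
        assert res.calibration is not None
        assert abs(res.calibration.c - truth.c_true) / truth.c_true < 0.02

    def test_no_match_errors(self):
        vent = VentilatorLog(timestamps=np.array([1000.0]), tidal_volume=np.array([400.0]))
        with pytest.raises(ValueError, match="matched"):
            calibrate_volume([self._breath(0, 8.0)], vent, fs=50.0)

    def test_nonpositive_volume_excluded_with_warning(self):
        vent = VentilatorLog(timestamps=np.array([1.0, 300.0]),
                             tidal_volume=np.array([0.0, 400.0]))
        with pytest.warns(UserWarning, match="excluded"):
            cal = calibrate_volume(
                [self._breath(0, 8.0), self._breath(int(299 * 50), 8.0)], vent, fs=50.0)
        assert cal.n_points == 1


class TestBreathParameters:
    def test_rsbi_definition(self, clean_minute):
        seq, mask, *_ = clean_minute
        breaths = segment_breaths(global_signal(seq, mask))
        b = breaths[5]
        cal = e.CalibrationFactor(c=400.0 / b.dz, n_points=1, method="single_point")
        bp = breath_parameters(seq, b, mask, cal)
        # rr = 15/min at vt 400 ml -> RSBI = 15 / 0.4 = 37.5
        assert bp.vt_ml == pytest.approx(400.0)
        assert bp.rsbi == pytest.approx(bp.rr / 0.4, rel=1e-12)
        assert bp.rsbi == pytest.approx(37.5, rel=0.02)
        assert bp.mv_l_min == pytest.approx(bp.rr * 0.4, rel=1e-12)

    def test_rapid_shallow_regime_crosses_classic_threshold(self):
        # 35/min at 333 ml is the textbook failing-weaning regime
        rr, vt_l = 35.0, 0.333
        assert rr / vt_l == pytest.approx(105.1, abs=0.1)

    def test_rsbi_algebraic_identity(self, clean_minute):
        seq, mask, *_ = clean_minute
        b = segment_breaths(global_signal(seq, mask))[2]
        cal = e.CalibrationFactor(c=100.0, n_points=1, method="single_point")
        bp = breath_parameters(seq, b, mask, cal)
        assert bp.rsbi == pytest.approx(
            bp.rr**2 * 1000.0 / (cal.c * b.dz * bp.rr), rel=1e-12)

    def test_uniform_map_splits_half_and_half(self, clean_minute):
        seq, mask, *_ = clean_minute
        b = segment_breaths(global_signal(seq, mask))[4]
        bp = breath_parameters(seq, b, mask)
        assert bp.frac_left + bp.frac_right == pytest.approx(1.0, abs=1e-12)
        assert bp.frac_ventral + bp.frac_dorsal == pytest.approx(1.0, abs=1e-12)
        assert bp.frac_left == pytest.approx(0.5, abs=0.01)
        assert np.isnan(bp.vt_ml)  # uncalibrated


class TestGIMonotoneDial:
    def test_pipeline_gi_rises_with_generator_gamma(self):
        gis = []
        for gamma in (0.0, 0.5, 1.0, 2.0):
            cfg = e.ScenarioConfig(noise_sd=0.0, cardiac_amp=0.0, gamma=gamma,
                                   phases=(e.PhaseSpec("pre", 30.0),), seed=12)
            seq, mask, _, _, _ = e.generate_scenario(cfg)
            b = segment_breaths(global_signal(seq, mask))[2]
            gis.append(compute_gi(tidal_image(seq, b, mask)))
        assert gis[0] == pytest.approx(0.0, abs=1e-12)
        assert all(b > a for a, b in zip(gis, gis[1:]))
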