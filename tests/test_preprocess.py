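"""Temporal preprocessing and motion-QC contracts."""
import numpy as np
import pytest

from netfalff.errors import ConfigError, DataError, DegenerateInputError, StageError
from netfalff.preprocess import (
    bandpass_fft,
    detrend_poly,
    discard_initial_volumes,
    framewise_displacement,
    friston24_expand,
    normalize_global_intensity,
    preprocess_subject,
    qc_evaluate,
    regress_nuisance,
)
from netfalff.types import MotionTrace, VertexTimeSeries


def _ts(data, tr=2.0):
    return VertexTimeSeries(np.asarray(data, dtype=float), tr=tr)


class TestDiscard:
    def test_equilibration_discard_keeps_tail(self, rng):
        ts = _ts(rng.standard_normal((243, 4)))
        out = discard_initial_volumes(ts, 5)
        assert out.n_timepoints == 238
        np.testing.assert_array_equal(out.data[0], ts.data[5])

    def test_zero_discard_is_identity(self, random_scan):
        out = discard_initial_volumes(random_scan, 0)
        np.testing.assert_array_equal(out.data, random_scan.data)

    def test_discarding_everything_is_an_error(self, rng):
        ts = _ts(rng.standard_normal((5, 3)))
        with pytest.raises(DataError):
            discard_initial_volumes(ts, 5)

    def test_stage_guard_refuses_silent_reapplication(self, random_scan):
        once = discard_initial_volumes(random_scan, 2)
        with pytest.raises(StageError):
            discard_initial_volumes(once, 2)
        forced = once.with_stage(once.data, "discard", force=True)
        assert forced.stage_tag.count("discard") == 2


class TestIntensityNormalization:
    def test_constant_scan_maps_to_target(self):
        out = normalize_global_intensity(_ts(np.full((10, 4), 5.0)))
        np.testing.assert_allclose(out.data, 10000.0)

    def test_grand_mean_hits_target(self, random_scan):
        out = normalize_global_intensity(random_scan)
        assert abs(out.data.mean() - 10000.0) < 1e-6

    def test_scale_invariance(self, random_scan):
        a = normalize_global_intensity(random_scan)
        b = normalize_global_intensity(
            VertexTimeSeries(random_scan.data * 3.0, tr=2.0)
        )
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_zero_scan_rejected(self):
        with pytest.raises(DegenerateInputError):
            normalize_global_intensity(_ts(np.zeros((8, 3))))


class TestFriston24:
    def test_zero_motion_expands_to_zero(self):
        out = friston24_expand(MotionTrace(np.zeros((10, 6))))
        assert out.shape == (10, 24)
        assert not out.any()

    def test_square_columns(self):
        params = np.full((6, 6), 2.0)
        out = friston24_expand(MotionTrace(params))
        np.testing.assert_array_equal(out[:, 6:12], np.full((6, 6), 4.0))

    def test_lag_structure(self):
        params = np.zeros((3, 6))
        params[:, 0] = [1.0, 2.0, 3.0]
        out = friston24_expand(MotionTrace(params))
        np.testing.assert_array_equal(out[:, 12], [0.0, 1.0, 2.0])
        np.testing.assert_array_equal(out[:, 18], [0.0, 1.0, 4.0])


class TestNuisanceRegression:
    def test_self_regression_annihilates(self, rng):
        data = rng.standard_normal((40, 5))
        out = regress_nuisance(_ts(data), data[:, 2])
        np.testing.assert_allclose(out.data[:, 2], 0.0, atol=1e-10)

    def test_orthogonal_nuisance_only_demeans(self, rng):
        t = np.arange(64)
        data = np.cos(2 * np.pi * 4 * t / 64)[:, None] + 3.0
        nuis = np.sin(2 * np.pi * 9 * t / 64)  # orthogonal on the DFT grid
        out = regress_nuisance(_ts(data), nuis)
        np.testing.assert_allclose(out.data, data - data.mean(axis=0), atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        design = rng.standard_normal((10, 3))
        y = rng.standard_normal((10, 1))
        full = np.column_stack([np.ones(10), design])
        beta = np.linalg.solve(full.T @ full, full.T @ y)
        expected = y - full @ beta
        out = regress_nuisance(_ts(y), design)
        np.testing.assert_allclose(out.data, expected, atol=1e-8)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        data = rng.standard_normal((50, 8))
        nuis = rng.standard_normal((50, 4))
        out = regress_nuisance(_ts(data), nuis)
        for j in range(4):
            c = np.abs(np.corrcoef(out.data.T, nuis[:, j])[-1, :-1])
            assert c.max() < 1e-6


class TestDetrend:
    def test_exact_polynomial_annihilation(self):
        t = np.linspace(0, 1, 50)
        data = (1.5 + 2.0 * t - 3.0 * t**2)[:, None]
        out = detrend_poly(_ts(data), 2)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_in_band_sinusoid_survives_quadratic_fit(self):
        t = np.arange(238)
        data = np.cos(2 * np.pi * 24 * t / 238)[:, None]  # ~0.05 Hz at tr=2
        out = detrend_poly(_ts(data), 2)
        rel = np.linalg.norm(out.data - data) / np.linalg.norm(data)
        assert rel < 0.05

    def test_order_zero_is_demeaning(self, rng):
        data = rng.standard_normal((30, 3)) + 7.0
        out = detrend_poly(_ts(data), 0)
        np.testing.assert_allclose(out.data, data - data.mean(axis=0), atol=1e-10)


class TestBandpass:
    def test_in_band_passthrough(self):
        t = np.arange(238)
        data = np.cos(2 * np.pi * 24 * t / 238)[:, None]  # on-grid, in band
        out = bandpass_fft(_ts(data))
        assert np.abs(out.data - data).max() / np.abs(data).max() < 1e-8

    def test_out_of_band_rejection(self):
        t = np.arange(238)
        data = np.cos(2 * np.pi * 95 * t / 238)[:, None]  # ~0.2 Hz
        out = bandpass_fft(_ts(data))
        assert np.abs(out.data).max() / np.abs(data).max() < 1e-8

    def test_parseval_half_power_split(self):
        t = np.arange(238)
        data = (np.cos(2 * np.pi * 24 * t / 238) + np.cos(2 * np.pi * 95 * t / 238))[:, None]
        out = bandpass_fft(_ts(data))
        p_in = (out.data**2).sum()
        p_tot = ((data - data.mean()) ** 2).sum()
        assert abs(p_in / p_tot - 0.5) < 1e-8

    def test_variance_never_grows(self, rng):
        data = rng.standard_normal((100, 10))
        out = bandpass_fft(_ts(data))
        assert out.data.var() <= data.var() + 1e-12

    def test_empty_band_is_config_error(self, rng):
        ts = _ts(rng.standard_normal((10, 2)), tr=0.1)
        with pytest.raises(ConfigError):
            bandpass_fft(ts, 0.01, 0.1)


class TestMotionQC:
    def test_zero_motion_all_metrics_zero(self):
        motion = MotionTrace(np.zeros((20, 6)))
        fd, mean_fd, rms_fd = framewise_displacement(motion)
        assert not fd.any() and mean_fd == 0.0 and rms_fd == 0.0
        rec = qc_evaluate(motion)
        assert rec.max_tran == rec.max_rot == rec.mean_fd == 0.0
        assert rec.passed

    def test_fd_hand_computed_case(self):
        params = np.zeros((2, 6))
        params[1] = [0.1, -0.2, 0.05, 0.002, 0.0, -0.001]
        fd, mean_fd, _ = framewise_displacement(MotionTrace(params))
        assert fd[0] == 0.0
        assert abs(fd[1] - 0.5) < 1e-12
        assert abs(mean_fd - 0.5) < 1e-12

    def test_fd_homogeneity(self, rng):
        params = np.cumsum(rng.standard_normal((15, 6)) * 0.01, axis=0)
        fd1, _, _ = framewise_displacement(MotionTrace(params))
        fd2, _, _ = framewise_displacement(MotionTrace(2 * params))
        np.testing.assert_allclose(fd2, 2 * fd1, atol=1e-12)

    def test_max_translation_from_first_frame(self):
        params = np.zeros((10, 6))
        params[:, 0] = np.linspace(0, 3.0, 10)
        rec = qc_evaluate(MotionTrace(params))
        assert abs(rec.max_tran - 3.0) < 1e-12
        assert not rec.passes["max_tran"]  # strict < 3 mm

    def test_rotation_reported_in_degrees(self):
        params = np.zeros((5, 6))
        params[-1, 3] = 0.0524
        rec = qc_evaluate(MotionTrace(params))
        assert abs(rec.max_rot - np.degrees(0.0524)) < 1e-9
        assert abs(rec.max_rot - 3.0) < 0.01


class TestChain:
    def test_default_chain_orders_and_tags(self, rng):
        data = rng.standard_normal((69, 20)) + 1000.0
        ts = VertexTimeSeries(data, tr=2.0, subject_id="s1")
        motion = MotionTrace(np.cumsum(rng.standard_normal((69, 6)) * 0.01, axis=0))
        res = preprocess_subject(ts, motion, n_discard=5)
        assert res.filtered.stage_tag[-1] == "bandpass"
        assert res.unfiltered.stage_tag[-1] == "detrend"
        assert res.filtered.n_timepoints == 64
        assert res.qc is not None

    def test_bandpass_must_be_last(self, random_scan):
        with pytest.raises(ConfigError):
            preprocess_subject(random_scan, order=("bandpass", "detrend"))
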