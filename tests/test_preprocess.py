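"""Signal-cleaning unit tests against closed-form and OLS oracles."""

import numpy as np
import pytest

from connectonet import preprocess as prep
from connectonet import synth
from connectonet.errors import (
    AllFramesCensoredError,
    DimensionMismatchError,
    InvalidBandError,
)


def make_ts(values, tr=2.0):
    values = np.asarray(values, dtype=float)
    labels = [f"R{i}" for i in range(values.shape[1])]
    return prep.ROITimeSeries(values, tr, labels)


class TestDetrend:
    def test_constant_and_ramp_channels_vanish(self):
        t = np.arange(100.0)
        ts = make_ts(np.column_stack([np.full(100, 3.0), 2.0 + 0.5 * t]))
        out = prep.linear_detrend(ts)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_matches_ols_residual_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(240.0)
        x = np.sin(0.3 * t)[:, None] + 0.01 * t[:, None] + rng.normal(size=(240, 5))
        design = np.column_stack([np.ones(240), t])
        beta = np.linalg.lstsq(design, x, rcond=None)[0]
        oracle = x - design @ beta
        out = prep.linear_detrend(make_ts(x))
        assert np.abs(out.values - oracle).max() < 1e-10

    def test_output_orthogonal_to_trend(self):
        rng = np.random.default_rng(1)
        out = prep.linear_detrend(make_ts(rng.normal(size=(50, 3))))
        t = np.arange(50.0)
        assert np.abs(out.values.sum(axis=0)).max() < 1e-8
        assert np.abs(t @ out.values).max() < 1e-6


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(240) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)  # exact DFT bin at TR 2 s, 240 frames
        out = prep.bandpass(make_ts(x[:, None]))
        assert (out.values**2).sum() >= 0.99 * (x**2).sum()

    def test_out_of_band_sinusoid_rejected(self):
        t = np.arange(240) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        out = prep.bandpass(make_ts(x[:, None]))
        assert (out.values**2).sum() <= 1e-6 * (x**2).sum()

    def test_dc_channel_zeroed(self):
        out = prep.bandpass(make_ts(np.full((240, 2), 7.0)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        ts = make_ts(rng.normal(size=(240, 4)))
        once = prep.bandpass(ts)
        twice = prep.bandpass(once)
        assert np.abs(once.values - twice.values).max() < 1e-10

    def test_invalid_band_rejected(self):
        ts = make_ts(np.zeros((240, 1)))
        with pytest.raises(InvalidBandError):
            prep.bandpass(ts, 0.08, 0.01)
        with pytest.raises(InvalidBandError):
            prep.bandpass(ts, 0.01, 0.5)  # above Nyquist = 0.25 Hz


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        out = prep.friston24(prep.MotionParams(np.zeros((20, 6))))
        assert out.shape == (20, 24)
        np.testing.assert_array_equal(out, 0.0)

    def test_lag_shift_semantics(self):
        m = np.zeros((10, 6))
        m[4, 2] = 1.0  # impulse in parameter 2 at frame 4
        out = prep.friston24(prep.MotionParams(m))
        assert out[4, 2] == 1.0
        assert out[5, 6 + 2] == 1.0  # lag column
        assert out[0, 6:12].sum() == 0.0  # zero-filled first lag row

    def test_squared_columns(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(15, 6))
        out = prep.friston24(prep.MotionParams(m))
        np.testing.assert_allclose(out[:, 12:24], out[:, :12] ** 2, atol=1e-15)


class TestNuisanceRegress:
    def test_channel_regressed_on_itself_vanishes(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(60, 1))
        out = prep.nuisance_regress(make_ts(x), x)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-10)

    def test_empty_regressors_demean(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 3)) + 5.0
        out = prep.nuisance_regress(make_ts(x), np.empty((60, 0)))
        np.testing.assert_allclose(out.values, x - x.mean(axis=0), atol=1e-10)

    def test_residuals_orthogonal_to_unit_norm_columns(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(120, 8))
        reg = rng.normal(size=(120, 5))
        out = prep.nuisance_regress(make_ts(x), reg)
        unit = reg / np.linalg.norm(reg, axis=0)
        assert np.abs(unit.T @ out.values).max() < 1e-8

    def test_rank_deficient_design_allowed(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 2))
        reg = rng.normal(size=(50, 2))
        reg = np.hstack([reg, reg])  # duplicated columns
        out = prep.nuisance_regress(make_ts(x), reg)
        unit = reg / np.linalg.norm(reg, axis=0)
        assert np.abs(unit.T @ out.values).max() < 1e-8

    def test_row_mismatch_rejected(self):
        with pytest.raises(DimensionMismatchError):
            prep.nuisance_regress(make_ts(np.zeros((50, 2))), np.zeros((40, 3)))


def _fd_sphere_oracle(params_prev, params_cur, radius=80.0, n=200_000, seed=0):
    """Monte-Carlo RMS displacement of points in a ball under the frame change."""
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal((n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(size=n) ** (1 / 3)
    pts = direction * r[:, None]
    m_prev = prep._rigid_affine(np.asarray(params_prev, float))
    m_cur = prep._rigid_affine(np.asarray(params_cur, float))
    diff = m_cur @ np.linalg.inv(m_prev) - np.eye(4)
    disp = pts @ diff[:3, :3].T + diff[:3, 3]
    return np.sqrt((disp**2).sum(axis=1).mean())


class TestFDJenkinson:
    def test_zero_motion(self):
        fd = prep.fd_jenkinson(prep.MotionParams(np.zeros((10, 6))))
        np.testing.assert_array_equal(fd, 0.0)

    def test_pure_translation_step(self):
        m = np.zeros((3, 6))
        m[2, 0] = 0.3
        fd = prep.fd_jenkinson(prep.MotionParams(m))
        assert fd[2] == pytest.approx(0.3, abs=1e-12)
        assert fd[0] == fd[1] == 0.0

    @pytest.mark.parametrize("axis", [3, 4, 5])
    def test_small_rotation_matches_sphere_integration(self, axis):
        m = np.zeros((2, 6))
        m[1, axis] = 0.004  # radians
        fd = prep.fd_jenkinson(prep.MotionParams(m))
        oracle = _fd_sphere_oracle(m[0], m[1])
        assert fd[1] == pytest.approx(oracle, rel=0.01)

    def test_mixed_motion_matches_sphere_integration(self):
        rng = np.random.default_rng(8)
        m = np.zeros((2, 6))
        m[1, :3] = rng.normal(scale=0.2, size=3)
        m[1, 3:] = rng.normal(scale=0.003, size=3)
        fd = prep.fd_jenkinson(prep.MotionParams(m))
        assert fd[1] == pytest.approx(_fd_sphere_oracle(m[0], m[1]), rel=0.01)

    def test_invariant_to_constant_translation_offset(self):
        # Exact when rotations are fixed (the frame-to-frame transform then
        # depends only on translation differences) ...
        rng = np.random.default_rng(9)
        m = np.zeros((12, 6))
        m[:, :3] = rng.normal(scale=0.1, size=(12, 3))
        shifted = m.copy()
        shifted[:, :3] += 5.0
        fd1 = prep.fd_jenkinson(prep.MotionParams(m))
        fd2 = prep.fd_jenkinson(prep.MotionParams(shifted))
        np.testing.assert_allclose(fd1, fd2, atol=1e-9)
        # ... and to first order when rotations vary (the rotation part of
        # the frame difference couples with the absolute translation).
        m[:, 3:] = rng.normal(scale=0.002, size=(12, 3))
        shifted = m.copy()
        shifted[:, :3] += 5.0
        fd1 = prep.fd_jenkinson(prep.MotionParams(m))
        fd2 = prep.fd_jenkinson(prep.MotionParams(shifted))
        np.testing.assert_allclose(fd1[1:], fd2[1:], rtol=0.15)


class TestDVARS:
    def test_constant_series(self):
        assert prep.dvars(make_ts(np.full((20, 5), 2.0))).max() == 0.0

    def test_single_channel_step(self):
        v = 16
        x = np.zeros((30, v))
        x[10:, 0] = 4.0  # step of h=4 at frame 10 in one of V channels
        d = prep.dvars(make_ts(x))
        assert d[10] == pytest.approx(4.0 / np.sqrt(v), abs=1e-12)
        assert d[11] == 0.0

    def test_iid_noise_level(self):
        rng = np.random.default_rng(10)
        sigma = 1.7
        x = rng.normal(scale=sigma, size=(240, 94))
        d = prep.dvars(make_ts(x))
        assert d[1:].mean() == pytest.approx(sigma * np.sqrt(2), rel=0.05)


class TestScrub:
    def test_threshold_above_max_keeps_everything(self):
        rng = np.random.default_rng(11)
        ts = make_ts(rng.normal(size=(50, 4)))
        q = prep.frame_quality(ts)
        out, outq = prep.scrub(ts, q, q.dvars.max() + 1.0)
        assert out.n_volumes == 50 and outq.censored.sum() == 0

    def test_tiny_threshold_censors_all(self):
        rng = np.random.default_rng(12)
        ts = make_ts(rng.normal(size=(50, 4)))
        q = prep.frame_quality(ts)
        with pytest.raises(AllFramesCensoredError):
            prep.scrub(ts, q, 1e-12)

    def test_exactly_spiked_frames_removed(self):
        x = np.zeros((40, 4))
        spikes = [7, 19, 33]
        for s in spikes:
            x[s, :] = 50.0
        ts = make_ts(x)
        q = prep.frame_quality(ts)
        out, outq = prep.scrub(ts, q, 10.0)
        # each spike contaminates the frame itself and the one after
        expected = sorted({s for s in spikes} | {s + 1 for s in spikes})
        assert sorted(np.nonzero(outq.censored)[0].tolist()) == expected
        assert out.n_volumes == 40 - len(expected)


class TestCleanPipeline:
    def test_drift_removed_after_cleaning(self):
        design = synth.CohortDesign(
            n_group1=2, n_group2=2, n_rois=8, n_volumes=240,
            drift_amplitude=1.0, seed=21,
        )
        cohort = synth.generate_cohort(design)
        t = np.arange(240) * 2.0
        freq = synth.drift_frequency_hz(240, 2.0)
        for rec in cohort.subjects:
            cleaned = prep.clean(rec.series)
            for phase in (0.0, np.pi / 2):  # quadrature pair spans any phase
                drift = np.sin(2 * np.pi * freq * t + phase)
                c = np.corrcoef(np.column_stack([drift, cleaned.values]), rowvar=False)
                assert np.abs(c[0, 1:]).max() < 0.05

    def test_pipeline_equals_manual_stage_order(self):
        rng = np.random.default_rng(13)
        ts = make_ts(rng.normal(size=(120, 6)))
        motion = synth.generate_motion(120, 0.05, seed=3)
        manual = prep.nuisance_regress(
            prep.bandpass(prep.linear_detrend(ts)), prep.friston24(motion)
        )
        out = prep.clean(ts, motion=motion)
        np.testing.assert_allclose(out.values, manual.values, atol=1e-12)
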