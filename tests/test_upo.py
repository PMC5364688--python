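"""UPO extraction: interval detection, So transform, histogram peak."""

import numpy as np
import pytest

from oculofit.synthetic import JitterSpec, generate_pseudo_experimental_series
from oculofit.upo import (
    DelayEmbedding,
    ExtractionError,
    delay_embed,
    detect_cycle_intervals,
    extract_upo,
    extract_upo_cycle,
    find_period_peak,
    so_transform,
)


def sawtooth(period=1.0, n_cycles=8, fs=250.0, amp=3.0, fast_fraction=0.1):
    """Slow drift away from target with a fast resetting phase."""
    t = np.arange(int(n_cycles * period * fs)) / fs
    phase = (t % period) / period
    slow = np.where(phase < 1 - fast_fraction, -amp * phase / (1 - fast_fraction), 0.0)
    fast = np.where(
        phase >= 1 - fast_fraction,
        -amp + amp * (phase - (1 - fast_fraction)) / fast_fraction,
        0.0,
    )
    return t, slow + fast


class TestDetectCycleIntervals:
    def test_sawtooth_intervals(self):
        t, x = sawtooth()
        iv = detect_cycle_intervals(x, 250.0, smooth_window=0.0)
        assert np.all(np.abs(iv.intervals - 1.0) <= 1 / 250.0)

    def test_threshold_above_max_velocity_fails(self):
        t, x = sawtooth()
        with pytest.raises(ExtractionError):
            detect_cycle_intervals(x, 250.0, vthresh=1e6)

    def test_constructed_reset_times(self):
        fs = 1000.0
        t = np.arange(int(4.0 * fs)) / fs
        x = np.zeros_like(t)
        for reset in (1.0, 2.2, 3.1):
            x += 2.0 * np.clip((t - reset) / 0.005, 0.0, 1.0)  # 5 ms upward ramps
        iv = detect_cycle_intervals(x, fs, min_separation=0.5, smooth_window=0.0)
        np.testing.assert_allclose(iv.intervals, [1.2, 0.9], atol=5 / fs)

    def test_subsample_crossing_interpolation(self):
        t, x = sawtooth(period=0.997)
        iv = detect_cycle_intervals(x, 250.0, smooth_window=0.0)
        assert np.abs(np.mean(iv.intervals) - 0.997) < 1 / 250.0


class TestSoTransform:
    def _linear_surrogate(self, A, b, n=60, w0=(0.9, 0.7)):
        W = np.empty((n, 2))
        W[0] = w0
        for k in range(n - 1):
            W[k + 1] = A @ W[k] + b
        return DelayEmbedding(vectors=W, dimension=2)

    def test_linear_map_collapses_to_fixed_point(self):
        A = np.array([[0.3, 0.1], [-0.2, 0.4]])
        b = np.array([0.5, 0.6])
        emb = self._linear_surrogate(A, b)
        pts = so_transform(emb, jacobian=lambda w: A)
        fixed = np.linalg.solve(np.eye(2) - A, b)
        np.testing.assert_allclose(pts, np.tile(fixed, (len(pts), 1)), atol=1e-10)

    def test_constant_intervals_already_fixed(self):
        taus = np.full(30, 0.8)
        emb = delay_embed(taus, 2)
        pts = so_transform(emb)
        np.testing.assert_allclose(pts, 0.8, atol=1e-8)

    def test_unit_eigenvalue_skipped(self):
        A = np.eye(2)
        b = np.zeros(2)
        emb = self._linear_surrogate(A, b)
        with pytest.raises(ExtractionError):
            so_transform(emb, jacobian=lambda w: A)

    def test_estimated_jacobian_on_linear_data(self):
        # even without the exact Jacobian, the local linear fit recovers it
        A = np.array([[0.5, 0.0], [0.1, 0.3]])
        b = np.array([0.4, 0.5])
        rng = np.random.default_rng(0)
        W = np.empty((80, 2))
        W[0] = (0.9, 0.7)
        for k in range(79):
            W[k + 1] = A @ W[k] + b + 1e-4 * rng.standard_normal(2)
        pts = so_transform(DelayEmbedding(vectors=W, dimension=2))
        fixed = np.linalg.solve(np.eye(2) - A, b)
        assert np.median(np.abs(pts - fixed)) < 0.05


class TestFindPeriodPeak:
    def test_single_cluster(self):
        pts = np.full((10, 2), 0.8)
        tau = find_period_peak(pts, 0.5, 0.025)
        assert abs(tau - 0.8) <= 0.0125 + 1e-12

    def test_point_outside_tube_excluded(self):
        # |1.0 - 0.2| / sqrt(2) ~ 0.566 > 0.25, so the lone point is rejected
        with pytest.raises(ExtractionError):
            find_period_peak(np.array([[1.0, 0.2]]), 0.5, 0.025)

    def test_majority_cluster_wins(self):
        rng = np.random.default_rng(1)
        a = 0.8 + 0.002 * rng.standard_normal((60, 1))
        bpts = 1.1 + 0.002 * rng.standard_normal((40, 1))
        pts = np.vstack([np.hstack([a, a]), np.hstack([bpts, bpts])])
        tau = find_period_peak(pts, 0.5, 0.025)
        assert abs(tau - 0.8) <= 0.025

    def test_tie_broken_to_smaller_period(self):
        pts = np.array([[0.3, 0.3], [0.9, 0.9]])
        tau = find_period_peak(pts, 0.5, 0.025)
        assert tau < 0.32


class TestFullPipeline:
    def test_periodic_recording_recovers_period_exactly(self, target_cycle):
        spec = JitterSpec(n_cycles=30, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        upo = extract_upo(rec.gaze, rec.sampling_rate)
        assert abs(upo.cycle.period - target_cycle.period) <= 1.0 / rec.sampling_rate

    def test_upsampling_factor_sets_sample_interval(self, target_cycle):
        spec = JitterSpec(n_cycles=20, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        iv = detect_cycle_intervals(rec.gaze, rec.sampling_rate)
        from oculofit.upo import delay_embed, find_period_peak, so_transform

        tau = find_period_peak(so_transform(delay_embed(iv)), 0.5, 0.025)
        upo = extract_upo_cycle(rec.gaze, rec.sampling_rate, iv, tau, upsample_factor=10)
        assert upo.cycle.sample_interval == pytest.approx(0.0004)

    def test_no_candidate_within_tolerance_fails(self, target_cycle):
        spec = JitterSpec(n_cycles=20, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        iv = detect_cycle_intervals(rec.gaze, rec.sampling_rate)
        with pytest.raises(ExtractionError):
            extract_upo_cycle(rec.gaze, rec.sampling_rate, iv, tau_star=99.0)

    def test_fast_phase_oriented_rightward(self, target_cycle):
        spec = JitterSpec(n_cycles=20, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        for flip in (1.0, -1.0):
            rec = generate_pseudo_experimental_series(target_cycle, spec)
            upo = extract_upo(flip * rec.gaze, rec.sampling_rate)
            from oculofit.waveform import differentiate

            v = differentiate(upo.cycle.values, upo.cycle.sample_interval)
            assert v[np.argmax(np.abs(v))] > 0
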