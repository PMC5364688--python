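"""Synthetic target generation and pseudo-experimental recordings."""

import numpy as np
import pytest

from oculofit.fitness import nystagmus_objectives
from oculofit.integrate import SolverConfig
from oculofit.model import DEFAULT_BOUNDS, ModelParameters, initial_state
from oculofit.synthetic import (
    JitterSpec,
    OSCILLATORY_PRESETS,
    SACCADE_PRESET,
    TARGET_SOLVER,
    find_oscillatory_presets,
    generate_nystagmus_target,
    generate_pseudo_experimental_series,
    generate_saccade_targets,
)
from oculofit.upo import detect_cycle_intervals
from oculofit.waveform import extract_simulated_cycle

FAST_SOLVER = SolverConfig(rtol=1e-5, atol=1e-8)


class TestPresets:
    def test_at_least_four_presets_shipped(self):
        assert len(OSCILLATORY_PRESETS) >= 4

    def test_presets_within_default_bounds(self):
        for p in OSCILLATORY_PRESETS:
            assert DEFAULT_BOUNDS.contains(p)

    def test_presets_reintegrate_oscillatory(self):
        from oculofit.integrate import integrate

        for p in OSCILLATORY_PRESETS:
            traj = integrate(p, initial_state(1.5), FAST_SOLVER)
            res = extract_simulated_cycle(traj)
            assert res.oscillatory
            assert 0.1 <= res.cycle.period <= 2.0
            assert 0.5 <= res.cycle.peak_to_peak <= 10.0

    def test_discovery_is_deterministic(self):
        a = find_oscillatory_presets(n_samples=24, cfg=FAST_SOLVER, seed=20)
        b = find_oscillatory_presets(n_samples=24, cfg=FAST_SOLVER, seed=20)
        assert [tuple(p.free_array()) for p in a] == [tuple(p.free_array()) for p in b]
        for p in a:
            assert DEFAULT_BOUNDS.contains(p)


class TestNystagmusTarget:
    def test_round_trip_self_fit(self, preset, target_cycle):
        obj = nystagmus_objectives(preset, target_cycle)
        assert obj.components[0] <= 1e-3
        assert obj.components[1] <= target_cycle.sample_interval

    def test_deterministic(self, preset):
        a = generate_nystagmus_target(preset, TARGET_SOLVER)
        b = generate_nystagmus_target(preset, TARGET_SOLVER)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.period == b.period

    def test_non_oscillatory_parameters_rejected(self):
        quiet = ModelParameters(5.0, 30.0, 0.05, 1.0, 600.0, 9.0)
        with pytest.raises(ValueError, match="non-oscillatory"):
            generate_nystagmus_target(quiet, FAST_SOLVER)


class TestSaccadeTargets:
    def test_default_amplitudes_give_three_profiles(self, saccade_targets):
        assert saccade_targets.amplitudes == (5.0, 10.0, 20.0)

    def test_profiles_start_from_rest(self, saccade_targets):
        for prof in saccade_targets.profiles:
            assert prof.velocities[0] == 0.0
            assert prof.times[0] == 0.0

    def test_main_sequence_peak_velocity_increases(self, saccade_targets):
        peaks = [prof.peak_velocity for prof in saccade_targets.profiles]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_profiles_end_settled(self, saccade_targets):
        for prof in saccade_targets.profiles:
            assert abs(prof.velocities[-1]) < 1.0

    def test_degenerate_threshold_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_saccade_targets(SACCADE_PRESET, amplitudes=(5.0,), stop_threshold=1e5)

    def test_bad_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            generate_saccade_targets(SACCADE_PRESET, amplitudes=(10.0, 5.0))


class TestPseudoExperimentalSeries:
    def test_zero_jitter_is_strictly_periodic(self, target_cycle):
        spec = JitterSpec(n_cycles=10, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        np.testing.assert_allclose(np.diff(rec.cycle_boundaries), target_cycle.period, atol=1e-12)

    def test_fixed_seed_reproducible(self, target_cycle):
        spec = JitterSpec(n_cycles=10, seed=4)
        a = generate_pseudo_experimental_series(target_cycle, spec)
        b = generate_pseudo_experimental_series(target_cycle, spec)
        np.testing.assert_array_equal(a.gaze, b.gaze)

    def test_period_jitter_statistics(self, target_cycle):
        spec = JitterSpec(n_cycles=200, period_jitter_sd=0.03, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=9)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        assert np.std(rec.cycle_periods) == pytest.approx(0.03, rel=0.25)
        se = 0.03 / np.sqrt(200)
        assert abs(np.mean(rec.cycle_periods) - target_cycle.period) < 3 * se

    def test_detected_crossings_track_true_boundaries_at_zero_noise(self, target_cycle):
        spec = JitterSpec(n_cycles=20, period_jitter_sd=0.0, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=0)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        iv = detect_cycle_intervals(rec.gaze, rec.sampling_rate)
        # one crossing per cycle, at a constant phase offset from the true
        # boundaries: crossing-to-crossing intervals equal the true periods
        assert np.all(np.abs(iv.intervals - target_cycle.period) <= 1.0 / rec.sampling_rate)

    def test_detected_interval_mean_matches_generator(self, target_cycle):
        spec = JitterSpec(n_cycles=100, period_jitter_sd=0.03, amplitude_jitter_sd=0.0, noise_sd=0.0, seed=2)
        rec = generate_pseudo_experimental_series(target_cycle, spec)
        iv = detect_cycle_intervals(rec.gaze, rec.sampling_rate)
        se = 0.03 / np.sqrt(len(iv.intervals))
        assert abs(np.mean(iv.intervals) - target_cycle.period) < 2 * se + 1.0 / rec.sampling_rate
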