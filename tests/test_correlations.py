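import numpy as np
import pytest

from swarmalators import (
    BinnedCurve,
    FrequencySpec,
    ModelParams,
    RunSchedule,
    SwarmState,
    count_peaks,
    decay_radius,
    find_peaks,
    pair_correlation,
    phase_correlation,
    simulate,
    support_radius,
    velocity_autocorrelation,
)
from _oracles import (
    count_peaks_loop,
    pair_histogram_loop,
    phase_corr_loop,
    support_radius_loop,
    velocity_corr_loop,
)
from conftest import make_state


def simple_state(pos, phase=None):
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    phase = np.zeros(n) if phase is None else np.asarray(phase, dtype=float)
    return SwarmState(pos=pos, phase=phase, omega=np.ones(n), c=np.zeros(n), R=np.zeros(n))


class TestPairCorrelation:
    def test_single_pair_mass_in_one_bin(self):
        state = simple_state([[0, 0], [0.5, 0]])
        edges = np.arange(0, 1.01, 0.1)
        g = pair_correlation([state], edges)
        k = 5  # bin [0.5, 0.6)
        assert g.value[k] == pytest.approx(1 / 0.1)
        assert np.all(np.delete(g.value, k) == 0)
        assert g.count[k] == 2  # both ordered pairs

    def test_collinear_triplet_splits_mass_two_thirds_one_third(self):
        state = simple_state([[0, 0], [1, 0], [2, 0]])
        edges = np.arange(0, 2.6, 0.5)
        g = pair_correlation([state], edges)
        mass = g.value * g.widths
        assert mass[2] == pytest.approx(2 / 3)  # r = 1 (4 of 6 ordered pairs)
        assert mass[4] == pytest.approx(1 / 3)  # r = 2

    def test_matches_double_loop_oracle(self, rng):
        states = [make_state(rng, n=12) for _ in range(3)]
        edges = np.arange(0, 8.01, 0.5)
        g = pair_correlation(states, edges)
        value0, count0 = pair_histogram_loop(states, edges)
        assert np.allclose(g.value, value0, atol=1e-12)
        assert np.array_equal(g.count, count0)

    def test_total_mass_is_one_when_grid_covers_all_pairs(self, rng):
        state = make_state(rng, n=50)
        edges = np.arange(0, 20.01, 0.05)
        g = pair_correlation([state], edges)
        assert np.sum(g.value * g.widths) == pytest.approx(1.0)

    def test_invariant_under_rotation_and_translation(self, rng):
        state = make_state(rng, n=20)
        psi = 1.1
        rot = np.array([[np.cos(psi), -np.sin(psi)], [np.sin(psi), np.cos(psi)]])
        moved = state.copy()
        moved.pos = state.pos @ rot.T + np.array([3.0, -2.0])
        edges = np.arange(0, 10.01, 0.1)
        assert np.allclose(
            pair_correlation([state], edges).value,
            pair_correlation([moved], edges).value,
            atol=1e-12, equal_nan=True,
        )

    def test_zero_width_bins_rejected(self):
        state = simple_state([[0, 0], [1, 0]])
        with pytest.raises(ValueError, match="increasing"):
            pair_correlation([state], np.array([0.0, 0.5, 0.5, 1.0]))


class TestPhaseCorrelation:
    def test_synchronised_state_plateaus_at_one(self, rng):
        state = make_state(rng, n=30)
        state.phase = np.full(30, 0.4)
        curve = phase_correlation([state], np.arange(0, 10.01, 0.25))
        occupied = curve.count > 0
        assert np.allclose(curve.value[occupied], 1.0)

    def test_antiphase_pair_gives_minus_one(self):
        state = simple_state([[0, 0], [1, 0]], phase=[0.0, np.pi])
        curve = phase_correlation([state], np.arange(0, 2.01, 0.5))
        assert curve.value[2] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle_and_bounds(self, rng):
        states = [make_state(rng, n=12) for _ in range(2)]
        edges = np.arange(0, 8.01, 0.5)
        curve = phase_correlation(states, edges)
        value0, count0 = phase_corr_loop(states, edges)
        assert np.allclose(curve.value, value0, atol=1e-12, equal_nan=True)
        assert np.array_equal(curve.count, count0)
        occ = curve.count > 0
        assert np.all(curve.value[occ] >= -1) and np.all(curve.value[occ] <= 1)

    def test_invariant_under_global_phase_shift(self, rng):
        state = make_state(rng, n=20)
        shifted = state.copy()
        shifted.phase = shifted.phase + 2.2
        edges = np.arange(0, 10.01, 0.25)
        assert np.allclose(
            phase_correlation([state], edges).value,
            phase_correlation([shifted], edges).value,
            atol=1e-12, equal_nan=True,
        )

    def test_pooling_equals_count_weighted_average(self, rng):
        a, b = make_state(rng, n=10), make_state(rng, n=14)
        edges = np.arange(0, 8.01, 0.5)
        pooled = phase_correlation([a, b], edges)
        ca, cb = phase_correlation([a], edges), phase_correlation([b], edges)
        num = np.nan_to_num(ca.value) * ca.count + np.nan_to_num(cb.value) * cb.count
        den = ca.count + cb.count
        merged = np.where(den > 0, num / np.maximum(den, 1), np.nan)
        assert np.allclose(pooled.value, merged, atol=1e-12, equal_nan=True)


class TestVelocityAutocorrelation:
    def test_frozen_state_has_zero_correlation(self):
        state = simple_state([[0, 0], [2 / 3, 0]])
        frames = [state.copy() for _ in range(11)]
        for k, f in enumerate(frames):
            f.t = float(k)
        from swarmalators import Trajectory

        traj = Trajectory(frames=frames)
        curve = velocity_autocorrelation(traj, [0.0, 1.0, 2.0])
        assert np.allclose(curve.value, 0.0)

    def test_single_chiral_orbit_gives_cosine_decay(self):
        sched = RunSchedule(dt=0.01, T=40.0, n=1, record_stride=10, seed=1)
        traj = simulate(FrequencySpec("F1"), ModelParams(speed=1.0), sched)
        lags = np.arange(0, 6.3, 0.1)
        curve = velocity_autocorrelation(traj, lags)
        # uniform circular motion at |c| = 1: C(tau) ~ cos(tau)
        assert np.allclose(curve.value, np.cos(lags), atol=0.02)

    def test_matches_scalar_loop_oracle(self):
        sched = RunSchedule(dt=0.1, T=10.0, n=10, record_stride=10, seed=6)
        traj = simulate(FrequencySpec("F2"), ModelParams(J=0.5, K=0.5, d=0.2, speed=1.0), sched)
        times, vel = traj.frame_velocities()
        lags = [0.0, 1.0, 3.0]
        curve = velocity_autocorrelation(traj, lags)
        assert np.allclose(curve.value, velocity_corr_loop(times, vel, lags), atol=1e-12)

    def test_lag_off_grid_or_too_long_rejected(self):
        sched = RunSchedule(dt=0.1, T=5.0, n=4, record_stride=10, seed=6)
        traj = simulate(FrequencySpec("F2"), ModelParams(), sched)
        with pytest.raises(ValueError, match="multiple"):
            velocity_autocorrelation(traj, [0.37])
        with pytest.raises(ValueError, match="span"):
            velocity_autocorrelation(traj, [100.0])


def curve_from(values, width=0.1, counts=None):
    values = np.asarray(values, dtype=float)
    edges = width * np.arange(len(values) + 1)
    counts = np.ones_like(values) if counts is None else np.asarray(counts, dtype=float)
    return BinnedCurve(bin_edges=edges, value=values, count=counts)


class TestSupportAndPeaks:
    def test_single_occupied_bin_support_is_its_right_edge(self):
        curve = curve_from([0, 0, 0, 0, 0, 1.0, 0, 0], counts=[0, 0, 0, 0, 0, 2, 0, 0])
        assert support_radius(curve) == pytest.approx(0.6)

    def test_decaying_curve_crosses_threshold_where_expected(self):
        r = np.arange(0.05, 3.0, 0.1)
        vals = np.exp(-3 * r)  # crosses 1% of max near r = 1.58
        curve = curve_from(vals)
        assert support_radius(curve) == pytest.approx(1.6, abs=0.051)

    def test_support_matches_linear_scan_on_random_curves(self, rng):
        for _ in range(100):
            vals = rng.uniform(0, 1, 30) * (rng.uniform(0, 1, 30) > 0.3)
            counts = (vals > 0).astype(float)
            if not np.any(vals > 0):
                continue
            curve = curve_from(vals, counts=counts)
            expected = support_radius_loop(curve.bin_edges, vals, counts, 0.01)
            assert support_radius(curve) == pytest.approx(expected)

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            support_radius(curve_from([0.0, 0.0], counts=[0, 0]))

    def test_decay_radius_finds_last_excursion(self):
        vals = np.concatenate([np.full(10, 0.9), np.full(10, 0.05), [0.2], np.full(9, 0.01)])
        curve = curve_from(vals)
        assert decay_radius(curve, level=0.1) == pytest.approx(2.1)
        assert decay_radius(curve_from(np.full(5, 0.01)), level=0.1) == 0.0

    def test_three_bump_curve_counts_three_peaks(self):
        r = np.arange(0.025, 2.0, 0.05)
        vals = (1.5 - 0.4 * r) * (1 + np.cos(2 * np.pi * r / 0.5)) / 2
        curve = curve_from(vals, width=0.05)
        assert count_peaks(curve, (0, 2)) == 3
        radii, heights = find_peaks(curve, (0, 2))
        assert np.all(np.diff(heights) < 0)  # descending

    def test_monotone_curve_has_no_interior_peaks(self):
        curve = curve_from(np.linspace(1, 0.1, 20))
        assert count_peaks(curve, (0, 2)) == 0

    def test_peak_count_matches_exhaustive_scan(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 1, 25)
            curve = curve_from(vals)
            smoothed = np.convolve(np.pad(vals, 1, mode="edge"), np.ones(3) / 3, mode="valid")
            assert count_peaks(curve, (0, 2.5)) == count_peaks_loop(smoothed)

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError, match="three bins"):
            count_peaks(curve_from(np.ones(20)), (0, 0.15))
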