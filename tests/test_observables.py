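"""Trajectory metrics: activity, switching, fits, KL, synchronization."""

import numpy as np
import pytest

from camkii_switch import observables as obs
from camkii_switch.engine import Trajectory
from camkii_switch.network import assemble_network
from camkii_switch.params import Parameters, SystemConfig
from camkii_switch.stimulus import CaTrace


def _traj_from_counts(net, count_rows, dt=1.0):
    counts = np.asarray(count_rows, dtype=np.int64)
    times = np.arange(counts.shape[0]) * dt
    trace = CaTrace(np.array([0.0, times[-1] + dt]), np.array([0.08]))
    return Trajectory(times, counts, net.species, trace, 0, 0)


@pytest.fixture(scope="module")
def net():
    return assemble_network(Parameters(), SystemConfig(), with_exchange=True)


class TestActivityFraction:
    @pytest.mark.parametrize("state,expected", [
        ("x6y0", 0.0), ("x0y6", 1.0), ("x5y1", 0.0), ("x4y2", 1.0),
    ])
    def test_pure_populations(self, net, state, expected):
        row = np.zeros(net.n_species, dtype=np.int64)
        row[net.species_index(state)] = 12
        act = obs.activity_fraction(_traj_from_counts(net, [row, row]))
        assert np.all(act.total == expected)

    def test_mixed_counting(self, net):
        row = np.zeros(net.n_species, dtype=np.int64)
        row[net.species_index("x0y6")] = 3
        row[net.species_index("x6y0")] = 9
        act = obs.activity_fraction(_traj_from_counts(net, [row]))
        assert act.total[0] == pytest.approx(0.25)

    def test_complexed_rings_count_with_their_state(self, net):
        row = np.zeros(net.n_species, dtype=np.int64)
        row[net.species_index("PP1_x0y6")] = 2
        row[net.species_index("x6y0")] = 2
        act = obs.activity_fraction(_traj_from_counts(net, [row]))
        assert act.total[0] == pytest.approx(0.5)


class TestSwitchStats:
    def test_square_wave_residences(self):
        t = np.arange(0, 1000.0)
        v = (t // 100 % 2).astype(float)  # alternates 0/1 every 100 s
        st = obs.switch_stats(t, v)
        assert st.residence_on == pytest.approx(100.0)
        assert st.residence_off == pytest.approx(100.0)
        assert st.relaxation_time == pytest.approx(0.0, abs=1.01)
        assert st.n_transitions == 9
        assert not st.censored

    def test_monotone_ramp_single_transition(self):
        t = np.arange(0, 101.0)
        st = obs.switch_stats(t, 1.0 - t / 100.0)
        assert st.n_transitions == 1
        # relaxation = crossing time of the 0.2..0.8 band on a unit ramp
        assert st.relaxation_time == pytest.approx(60.0, abs=2.0)

    def test_constant_trace_censored(self):
        t = np.arange(0, 500.0)
        st = obs.switch_stats(t, np.ones_like(t))
        assert st.censored and st.n_transitions == 0
        assert st.residence_on == pytest.approx(t[-1] - t[0])
        assert st.on_fraction == 1.0

    def test_telegraph_residence_recovery(self, rng):
        """Mean residences of a telegraph process recovered within 10%."""
        lam_on, lam_off = 1 / 40.0, 1 / 60.0  # leave-rates
        t_tot, dt = 0.0, 0.5
        states, durations = [], []
        state = 1
        while len(durations) < 2000:
            lam = lam_on if state == 1 else lam_off
            d = rng.exponential(1 / lam)
            durations.append(d)
            states.append(state)
            state = 1 - state
        times = np.concatenate([[0.0], np.cumsum(durations)])
        grid = np.arange(0.0, times[-1], dt)
        vals = np.array(states)[np.searchsorted(times, grid, side="right") - 1]
        st = obs.switch_stats(grid, vals.astype(float), on_th=0.5 + 1e-9,
                              off_th=0.5 - 1e-9)
        assert st.residence_on == pytest.approx(40.0, rel=0.10)
        assert st.residence_off == pytest.approx(60.0, rel=0.10)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            obs.switch_stats(np.arange(5.0), np.zeros(5), on_th=0.2, off_th=0.8)


class TestSigmoid:
    def test_recover_synthetic_logistic(self, rng):
        x = np.linspace(4, 16, 9)
        y = 1.0 / (1.0 + np.exp(2.0 * (x - 10.0)))
        y = np.clip(y + rng.normal(0, 0.01, x.size), 0, 1)
        fit = obs.pp1_tolerance_curve(x, y)
        assert not fit.flagged
        assert fit.a == pytest.approx(1.0, abs=0.05)
        assert fit.k == pytest.approx(2.0, rel=0.2)
        assert fit.x0 == pytest.approx(10.0, rel=0.05)

    def test_degenerate_curve_flagged(self):
        fit = obs.pp1_tolerance_curve(np.arange(5.0), np.ones(5))
        assert fit.flagged


class TestRiseTimes:
    def test_linear_ramp(self):
        t = np.arange(0, 101.0)
        rt = obs.rise_times(t, t / 100.0, smooth_window=1)
        assert rt.onset == pytest.approx(10.0, abs=1.0)
        assert rt.rise == pytest.approx(80.0, abs=1.5)

    def test_flat_zero_censored(self):
        rt = obs.rise_times(np.arange(10.0), np.zeros(10))
        assert rt.censored

    def test_step_function_rises_instantly(self):
        v = np.concatenate([np.zeros(50), np.ones(50)])
        rt = obs.rise_times(np.arange(100.0), v, smooth_window=1)
        assert rt.rise == pytest.approx(0.0, abs=1e-9)


class TestSyncStrength:
    def test_identical_traces_fully_synchronized(self):
        t = np.arange(0, 400.0)
        v = (t // 50 % 2).astype(float)
        m = obs.sync_strength(t, np.stack([v, v, v], axis=1))
        assert m.ks == pytest.approx(1.0)

    def test_three_independent_switches(self, rng):
        """Independent symmetric switches agree 2/8 of the time: ks = 0.25."""
        n = 60000
        cols = [np.repeat(rng.integers(0, 2, n // 20), 20).astype(float)
                for _ in range(3)]
        m = obs.sync_strength(np.arange(n, dtype=float),
                              np.stack(cols, axis=1))
        assert m.ks == pytest.approx(0.25, abs=0.03)
        assert m.ti == pytest.approx(0.75, abs=0.03)

    def test_anticorrelated_pair(self):
        t = np.arange(0, 200.0)
        v = (t // 25 % 2).astype(float)
        m = obs.sync_strength(t, np.stack([v, 1 - v], axis=1))
        assert m.ks == pytest.approx(0.0, abs=0.02)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            obs.sync_strength(np.arange(5.0), np.ones((5, 1)))


class TestOccupancyKL:
    def test_identical_histograms_zero(self):
        h = np.array([5, 10, 3, 0, 2])
        assert obs.occupancy_kl(h, h) == 0.0

    def test_hand_computed_two_bin_case(self):
        """(0.5, 0.5) vs (0.9, 0.1) is 0.736 bits (no smoothing)."""
        kl = obs.occupancy_kl(np.array([50, 50]), np.array([90, 10]), alpha=0)
        assert kl == pytest.approx(0.736, abs=1e-3)

    def test_nonnegative_and_smoothing_monotone(self):
        a = np.array([100, 0, 0])
        b = np.array([0, 0, 100])
        kls = [obs.occupancy_kl(a, b, alpha=al) for al in (0.5, 1.0, 2.0)]
        assert all(k > 0 for k in kls)
        assert kls[0] > kls[1] > kls[2]

    def test_mismatched_support_rejected(self):
        with pytest.raises(ValueError):
            obs.occupancy_kl(np.ones(3), np.ones(4))


class TestDecayFits:
    def test_single_exponential_recovery(self):
        t = np.arange(0, 300.0)
        fit = obs.fit_decay(t, np.exp(-t / 50.0), model="single")
        assert fit.tau == pytest.approx(50.0, rel=0.01)

    def test_double_fixed_weight_recovery(self):
        t = np.arange(0, 500.0, 0.5)
        y = 0.74 * np.exp(-t / 8.0) + 0.26 * np.exp(-t / 90.0)
        fit = obs.fit_decay(t, y, model="double", fixed_weight=0.74)
        assert fit.tau_fast == pytest.approx(8.0, rel=0.05)
        assert fit.tau_slow == pytest.approx(90.0, rel=0.05)
        assert fit.P_fast == pytest.approx(0.74)

    def test_recovery_across_seeds_with_noise(self):
        """Parameter recovery within 5% across 20 noisy replicates."""
        t = np.arange(0, 400.0, 0.5)
        clean = 0.74 * np.exp(-t / 8.0) + 0.26 * np.exp(-t / 90.0)
        for seed in range(20):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.004,
                                                               t.size)
            fit = obs.fit_decay(t, noisy, model="double", fixed_weight=0.74,
                                floor_frac=None)
            assert fit.tau_fast == pytest.approx(8.0, rel=0.05)
            assert fit.tau_slow == pytest.approx(90.0, rel=0.05)

    def test_constant_trace_flagged(self):
        fit = obs.fit_decay(np.arange(50.0), np.ones(50), model="single")
        assert fit.flagged

    def test_fit_starts_at_trace_peak(self):
        """A pulse-aligned trace rising then decaying is fitted from its peak."""
        t = np.arange(0, 200.0)
        y = np.where(t < 5, t / 5.0, np.exp(-(t - 5) / 30.0))
        fit = obs.fit_decay(t, y, model="single")
        assert fit.tau == pytest.approx(30.0, rel=0.02)


class TestMixture:
    def test_endpoints_and_blend(self):
        f, s = np.array([1.0, 0.5]), np.array([0.2, 0.1])
        assert np.array_equal(obs.mix_populations(f, s, 1.0), f)
        assert np.array_equal(obs.mix_populations(f, s, 0.0), s)
        m = obs.mix_populations(f, s, 0.74)
        assert m[0] == pytest.approx(0.74 * 1.0 + 0.26 * 0.2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            obs.mix_populations(np.ones(3), np.ones(4), 0.5)
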