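"""Exactness and contracts of the Gillespie engine."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import null_space

from camkii_switch.engine import compile_system, run_ensemble, simulate
from camkii_switch.network import (Reaction, ReactionNetwork, Species,
                                   assemble_network)
from camkii_switch.params import Parameters, SystemConfig
from camkii_switch.stimulus import CaTrace, basal_protocol, realize


def _flat(t_end, ca=0.08):
    return CaTrace(np.array([0.0, t_end]), np.array([ca]))


def _net(species, reactions):
    return ReactionNetwork(list(species), list(reactions), Parameters(), 1.0)


class TestElementary:
    def test_empty_reaction_set_constant_counts(self):
        net = _net([Species("A", "pp1")], [])
        traj = simulate(compile_system(net), {"A": 7}, _flat(10.0), seed=0)
        assert np.all(traj.counts == 7)

    def test_single_molecule_decay_is_exponential(self):
        """A→∅ at rate λ: first-passage times follow Exponential(λ)."""
        lam = 2.0
        net = _net([Species("A", "pp1")],
                   [Reaction("decay", ("A",), (), rate=lam)])
        cs = compile_system(net)
        times = []
        for i in range(400):
            traj = simulate(cs, {"A": 1}, _flat(40.0), seed=i,
                            record_dt=0.005)
            gone = np.nonzero(traj.counts[:, 0] == 0)[0]
            assert gone.size > 0
            times.append(traj.times[gone[0]])
        res = stats.kstest(times, stats.expon(scale=1 / lam).cdf)
        assert res.pvalue > 0.01

    def test_two_state_toggle_stationary_occupancy(self):
        """A⇌B: stationary P(A) = k_b/(k_f + k_b) within binomial error."""
        kf, kb = 3.0, 1.0
        net = _net([Species("A", "pp1"), Species("B", "pp1")],
                   [Reaction("f", ("A",), ("B",), rate=kf),
                    Reaction("b", ("B",), ("A",), rate=kb)])
        traj = simulate(compile_system(net), {"A": 1}, _flat(4000.0), seed=3,
                        record_dt=0.05)
        p_a = traj.counts[2000:, 0].mean()
        expected = kb / (kf + kb)
        # effective sample size ~ number of switching cycles
        n_eff = 4000.0 / (1 / kf + 1 / kb)
        assert abs(p_a - expected) < 4 * np.sqrt(expected * (1 - expected) / n_eff)


class TestAgainstMasterEquation:
    def test_stationary_distribution_matches_cme_null_space(self):
        """A+B⇌C: SSA occupancy vs brute-force CME stationary vector.

        With A0=4, B0=6 the reachable states are n_C ∈ {0..4}; the chemical
        master equation generator is built exactly over those states and its
        null space compared with the time-averaged SSA occupancy
        (total variation < 0.02).
        """
        c_bind, k_unbind = 0.7, 2.0
        net = _net(
            [Species("A", "pp1"), Species("B", "pp1"), Species("C", "pp1")],
            [Reaction("bind", ("A", "B"), ("C",), rate=c_bind),
             Reaction("unbind", ("C",), ("A", "B"), rate=k_unbind)])
        A0, B0 = 4, 6
        n_states = A0 + 1  # n_C from 0 to A0
        G = np.zeros((n_states, n_states))
        for nc in range(n_states):
            na, nb = A0 - nc, B0 - nc
            if nc < A0:
                G[nc + 1, nc] += c_bind * na * nb
            if nc > 0:
                G[nc - 1, nc] += k_unbind * nc
        np.fill_diagonal(G, G.diagonal() - G.sum(axis=0))
        ns = null_space(G)
        p_exact = np.abs(ns[:, 0]) / np.abs(ns[:, 0]).sum()

        traj = simulate(compile_system(net), {"A": A0, "B": B0},
                        _flat(60000.0), seed=9, record_dt=0.05)
        nc_samples = traj.counts[10000:, 2]
        p_emp = np.bincount(nc_samples, minlength=n_states) / nc_samples.size
        assert 0.5 * np.abs(p_emp - p_exact).sum() < 0.02


class TestFullModel:
    def test_conservation_at_every_record(self, params, cfg):
        net = assemble_network(params, cfg, with_exchange=True)
        init = {"x0y6": 6, "x0y7": 6, "PP1": cfg.N_PP1}
        trace = realize(basal_protocol(0.080), 600.0, seed=2)
        traj = simulate(compile_system(net), init, trace, seed=4)
        w = net.conserved_weights()
        sub = traj.total(w["subunits"])
        pp1 = traj.total(w["pp1"])
        assert np.all(sub == 6 * 6 + 6 * 7)
        assert np.all(pp1 == cfg.N_PP1)
        assert np.all(traj.counts >= 0)

    def test_no_phospho_without_calcium_drive(self, params, cfg):
        """At vanishing Ca every phosphorylation propensity is ~0."""
        p = params.replace(vt=0.0)
        net = assemble_network(p, cfg, with_exchange=False)
        traj = simulate(compile_system(net), {"x6y0": 12, "PP1": 10},
                        _flat(500.0, ca=1e-6), seed=1)
        assert np.all(traj.column("x6y0") == 12)

    def test_saturating_calcium_fully_phosphorylates(self, params, cfg):
        net = assemble_network(params.replace(vt=0.0), cfg,
                               with_exchange=False)
        traj = simulate(compile_system(net), {"x6y0": 12}, _flat(60.0, ca=50.0),
                        seed=1)
        assert traj.column("x0y6")[-1] == 12

    def test_ca_breakpoint_refresh(self, params, cfg):
        """Phosphorylation only proceeds during the high-Ca segment."""
        net = assemble_network(params.replace(vt=0.0), cfg,
                               with_exchange=False)
        trace = CaTrace(np.array([0.0, 100.0, 160.0, 400.0]),
                        np.array([1e-6, 50.0, 1e-6]))
        traj = simulate(compile_system(net), {"x6y0": 12}, trace, seed=6)
        n_full = traj.column("x0y6")
        assert n_full[np.searchsorted(traj.times, 99.0)] == 0
        assert n_full[np.searchsorted(traj.times, 200.0)] == 12
        assert n_full[-1] == 12


class TestDeterminism:
    def test_same_seed_identical_trajectory(self, params, cfg):
        net = assemble_network(params, cfg)
        cs = compile_system(net)
        trace = realize(basal_protocol(0.080), 200.0, seed=5)
        init = {"x0y6": 6, "x0y7": 6, "PP1": 30}
        a = simulate(cs, init, trace, seed=7)
        b = simulate(cs, init, trace, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = simulate(cs, init, trace, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_ensemble_reproducible_and_independent(self, params, cfg):
        net = assemble_network(params, cfg)
        cs = compile_system(net)
        init = {"x0y6": 6, "x0y7": 6, "PP1": 30}
        e1 = run_ensemble(cs, init, basal_protocol(0.080), 100.0, 2, 17)
        e2 = run_ensemble(cs, init, basal_protocol(0.080), 100.0, 2, 17)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.counts, b.counts)
        assert not np.array_equal(e1[0].counts, e1[1].counts)

    def test_ensemble_mean_matches_ode_for_linear_process(self):
        """Birth-death X→∅, ∅→... pure decay ensemble mean follows the ODE."""
        lam = 0.5
        net = _net([Species("A", "pp1")],
                   [Reaction("d", ("A",), (), rate=lam)])
        cs = compile_system(net)
        runs = run_ensemble(cs, {"A": 200}, _flat(8.0), 8.0, 30, 100,
                            record_dt=0.5)
        mean = np.mean([r.counts[:, 0] for r in runs], axis=0)
        t = runs[0].times
        expected = 200 * np.exp(-lam * t)
        sd = np.sqrt(200 * np.exp(-lam * t) * (1 - np.exp(-lam * t)) + 1e-9)
        assert np.all(np.abs(mean - expected) < 4 * sd / np.sqrt(30) + 1.0)
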