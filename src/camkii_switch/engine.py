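"""Exact stochastic simulation of a reaction network under a piecewise-constant Ca drive.

Gillespie's direct method, statistically exact within each constant-Ca
window.  At every Ca breakpoint the Ca-dependent propensities are refreshed
and the pending waiting time is re-drawn; because exponential waiting times
are memoryless given refreshed propensities, the restart is exact.

The inner loop is compiled with numba.  Channel selection uses a binary
sum-tree (O(log R) update and sampling), rebuilt periodically to cancel
floating-point drift.  Randomness comes from an inlined splitmix64 stream so
trajectories are bit-reproducible for a given seed across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit, uint64, float64

from .network import ReactionNetwork, Species, CA_LAWS
from .params import Parameters
from .stimulus import CaTrace

__all__ = ["CompiledSystem", "Trajectory", "compile_system", "simulate",
           "run_ensemble"]

_LAW_ID = {law: i for i, law in enumerate(CA_LAWS)}  # v1=0, v2=1, i1p_assoc=2

_REBUILD_EVERY = 1 << 20


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True, inline="always")
def _rand_u(state):
    s = state[0] + uint64(0x9E3779B97F4A7C15)
    state[0] = s
    z = (s ^ (s >> uint64(30))) * uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> uint64(27))) * uint64(0x94D049BB133111EB)
    z = z ^ (z >> uint64(31))
    return (float64(z >> uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _law_values(ca, pk):
    """(v1, v2, k3*I1P) at Ca level ``ca``; pk packs the rate parameters."""
    h1 = (ca / pk[1]) ** pk[2]
    sat = h1 / (1.0 + h1)
    v2 = pk[0] * sat
    v1 = pk[0] * sat * sat
    h2 = (ca / pk[4]) ** pk[5]
    if pk[7] > 0.5:
        i1p = pk[3] * (1.0 + h2) / h2
    else:
        i1p = pk[3] * h2 / (1.0 + h2)
    return v1, v2, pk[6] * i1p


@njit(cache=True, inline="always")
def _propensity(r, counts, r_rate, r_i, r_j, r_law, g0, g1, g2):
    a = r_rate[r] * counts[r_i[r]]
    j = r_j[r]
    if j >= 0:
        a *= counts[j]
    law = r_law[r]
    if law == 0:
        a *= g0
    elif law == 1:
        a *= g1
    elif law == 2:
        a *= g2
    return a


@njit(cache=True, inline="always")
def _tree_set(tree, P, i, val):
    idx = P + i
    tree[idx] = val
    idx >>= 1
    while idx >= 1:
        tree[idx] = tree[2 * idx] + tree[2 * idx + 1]
        idx >>= 1


@njit(cache=True)
def _tree_rebuild(tree, P, R, counts, r_rate, r_i, r_j, r_law, g0, g1, g2):
    for i in range(2 * P):
        tree[i] = 0.0
    for r in range(R):
        tree[P + r] = _propensity(r, counts, r_rate, r_i, r_j, r_law,
                                  g0, g1, g2)
    for idx in range(P - 1, 0, -1):
        tree[idx] = tree[2 * idx] + tree[2 * idx + 1]


@njit(cache=True, inline="always")
def _tree_sample(tree, P, R, u):
    target = u * tree[1]
    idx = 1
    while idx < P:
        left = tree[2 * idx]
        if target < left:
            idx = 2 * idx
        else:
            target -= left
            idx = 2 * idx + 1
    r = idx - P
    if r >= R:
        r = R - 1
    return r


@njit(cache=True)
def _ssa_core(counts, t_end, rec_times, rec,
              r_rate, r_i, r_j, r_law,
              st_ptr, st_sp, st_dl,
              dep_ptr, dep_idx, ca_idx,
              ca_bp, ca_lv, pk, seed, max_events):
    """Direct-method SSA.  Returns (status, n_events, n_recorded).

    status: 0 ok, 1 event budget exhausted, 2 negative count (network bug).
    """
    R = r_rate.size
    P = 1
    while P < R:
        P <<= 1
    tree = np.zeros(2 * P, dtype=np.float64)
    state = np.empty(1, dtype=np.uint64)
    state[0] = seed

    seg = 0
    g0, g1, g2 = _law_values(ca_lv[seg], pk)
    _tree_rebuild(tree, P, R, counts, r_rate, r_i, r_j, r_law, g0, g1, g2)

    n_rec = rec_times.size
    i_rec = 0
    t = 0.0
    events = uint64(0)
    status = 0

    while t < t_end:
        seg_end = t_end
        if seg + 1 < ca_bp.size and ca_bp[seg + 1] < t_end:
            seg_end = ca_bp[seg + 1]
        a_tot = tree[1]
        if a_tot <= 1e-300:
            t_next = seg_end + 1.0
        else:
            t_next = t - np.log(_rand_u(state)) / a_tot
        if t_next >= seg_end:
            while i_rec < n_rec and rec_times[i_rec] <= seg_end + 1e-12:
                for s in range(counts.size):
                    rec[i_rec, s] = counts[s]
                i_rec += 1
            t = seg_end
            if seg + 1 < ca_lv.size and seg_end < t_end:
                seg += 1
                g0, g1, g2 = _law_values(ca_lv[seg], pk)
                for k in range(ca_idx.size):
                    r = ca_idx[k]
                    _tree_set(tree, P, r,
                              _propensity(r, counts, r_rate, r_i, r_j, r_law,
                                          g0, g1, g2))
            else:
                break
            continue
        while i_rec < n_rec and rec_times[i_rec] < t_next:
            for s in range(counts.size):
                rec[i_rec, s] = counts[s]
            i_rec += 1
        t = t_next
        r = _tree_sample(tree, P, R, _rand_u(state))
        for k in range(st_ptr[r], st_ptr[r + 1]):
            sp = st_sp[k]
            counts[sp] += st_dl[k]
            if counts[sp] < 0:
                return 2, events, i_rec
        for k in range(dep_ptr[r], dep_ptr[r + 1]):
            d = dep_idx[k]
            _tree_set(tree, P, d,
                      _propensity(d, counts, r_rate, r_i, r_j, r_law,
                                  g0, g1, g2))
        events += uint64(1)
        if events >= max_events:
            return 1, events, i_rec
        if events % _REBUILD_EVERY == 0:
            _tree_rebuild(tree, P, R, counts, r_rate, r_i, r_j, r_law,
                          g0, g1, g2)

    while i_rec < n_rec:
        for s in range(counts.size):
            rec[i_rec, s] = counts[s]
        i_rec += 1
    return status, events, i_rec


# ---------------------------------------------------------------------------
# compilation of a network to flat arrays

@dataclass
class CompiledSystem:
    """Flat-array form of a ReactionNetwork, ready for the SSA core."""

    network: ReactionNetwork
    r_rate: np.ndarray
    r_i: np.ndarray
    r_j: np.ndarray
    r_law: np.ndarray
    st_ptr: np.ndarray
    st_sp: np.ndarray
    st_dl: np.ndarray
    dep_ptr: np.ndarray
    dep_idx: np.ndarray
    ca_idx: np.ndarray
    pk: np.ndarray

    @property
    def species(self) -> list[Species]:
        return self.network.species

    @property
    def n_species(self) -> int:
        return self.network.n_species


def _pack_params(p: Parameters) -> np.ndarray:
    return np.array([p.k1, p.KH1, p.nH1, p.I1 * p.vPKA_over_vCaN,
                     p.KH2, p.nH2, p.k3,
                     1.0 if p.i1p_mode == "decreasing" else 0.0])


def compile_system(net: ReactionNetwork) -> CompiledSystem:
    R = len(net.reactions)
    r_rate = np.array([r.rate for r in net.reactions], dtype=np.float64)
    r_i = np.array([net.species_index(r.reactants[0]) for r in net.reactions],
                   dtype=np.int64)
    r_j = np.array([net.species_index(r.reactants[1]) if r.order == 2 else -1
                    for r in net.reactions], dtype=np.int64)
    r_law = np.array([_LAW_ID[r.ca_law] if r.ca_law else -1
                      for r in net.reactions], dtype=np.int64)

    st_ptr = [0]
    st_sp: list[int] = []
    st_dl: list[int] = []
    changed_by: list[list[int]] = []
    for r in net.reactions:
        delta: dict[int, int] = {}
        for name in r.reactants:
            i = net.species_index(name)
            delta[i] = delta.get(i, 0) - 1
        for name in r.products:
            i = net.species_index(name)
            delta[i] = delta.get(i, 0) + 1
        nz = sorted((i, d) for i, d in delta.items() if d != 0)
        st_sp.extend(i for i, _ in nz)
        st_dl.extend(d for _, d in nz)
        st_ptr.append(len(st_sp))
        changed_by.append([i for i, _ in nz])

    by_reactant: dict[int, list[int]] = {}
    for j, r in enumerate(net.reactions):
        for name in r.reactants:
            by_reactant.setdefault(net.species_index(name), []).append(j)
    dep_ptr = [0]
    dep_idx: list[int] = []
    for j in range(R):
        deps: set[int] = set()
        for sp in changed_by[j]:
            deps.update(by_reactant.get(sp, ()))
        dep_idx.extend(sorted(deps))
        dep_ptr.append(len(dep_idx))

    ca_idx = np.nonzero(r_law >= 0)[0].astype(np.int64)
    return CompiledSystem(
        net, r_rate, r_i, r_j, r_law,
        np.array(st_ptr, dtype=np.int64), np.array(st_sp, dtype=np.int64),
        np.array(st_dl, dtype=np.int64),
        np.array(dep_ptr, dtype=np.int64), np.array(dep_idx, dtype=np.int64),
        ca_idx, _pack_params(net.params))


# ---------------------------------------------------------------------------
# trajectories

@dataclass
class Trajectory:
    """Time-sampled counts of every species, plus the driving Ca trace."""

    times: np.ndarray          # (T,)
    counts: np.ndarray         # (T, n_species) int64
    species: list[Species]
    ca: CaTrace
    seed: int
    n_events: int
    metadata: dict = field(default_factory=dict)

    def column(self, name: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.species) if s.name == name]
        if not idx:
            raise KeyError(name)
        return self.counts[:, idx[0]]

    def total(self, weights: np.ndarray) -> np.ndarray:
        """Weighted total count over species at each record."""
        return self.counts @ weights

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame(self.counts, columns=[s.name for s in self.species])
        df.insert(0, "time", self.times)
        return df


def simulate(system: CompiledSystem | ReactionNetwork,
             initial_counts: np.ndarray | dict[str, int],
             ca_trace: CaTrace,
             t_end: Optional[float] = None,
             seed: int = 0,
             record_dt: float = 1.0,
             max_events: int = 2_000_000_000) -> Trajectory:
    """Run one SSA trajectory and sample counts every ``record_dt`` seconds."""
    if isinstance(system, ReactionNetwork):
        system = compile_system(system)
    if t_end is None:
        t_end = ca_trace.t_end
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if t_end > ca_trace.t_end + 1e-9:
        raise ValueError("ca_trace does not cover [0, t_end]")

    if isinstance(initial_counts, dict):
        counts = np.zeros(system.n_species, dtype=np.int64)
        for name, n in initial_counts.items():
            counts[system.network.species_index(name)] = n
    else:
        counts = np.array(initial_counts, dtype=np.int64).copy()
        if counts.size != system.n_species:
            raise ValueError("initial_counts has wrong length")
    if np.any(counts < 0):
        raise ValueError("initial counts must be >= 0")

    rec_times = np.arange(0.0, t_end + record_dt * 0.5, record_dt)
    rec = np.zeros((rec_times.size, system.n_species), dtype=np.int64)
    seed64 = np.uint64((int(seed) * 0x9E3779B9 + 0x1234567) % (1 << 63))

    status, n_events, n_rec = _ssa_core(
        counts, float(t_end), rec_times, rec,
        system.r_rate, system.r_i, system.r_j, system.r_law,
        system.st_ptr, system.st_sp, system.st_dl,
        system.dep_ptr, system.dep_idx, system.ca_idx,
        ca_trace.breakpoints, ca_trace.levels, system.pk,
        seed64, np.uint64(max_events))
    if status == 2:
        raise RuntimeError("negative species count: reaction network bug")
    if status == 1:
        raise RuntimeError(f"event budget {max_events} exhausted at "
                           f"{rec_times[max(n_rec - 1, 0)]:.1f} s")
    return Trajectory(rec_times, rec, system.species, ca_trace, int(seed),
                      int(n_events))


def run_ensemble(system: CompiledSystem | ReactionNetwork,
                 initial_counts: np.ndarray | dict[str, int],
                 protocol,
                 t_end: float,
                 n_runs: int,
                 base_seed: int,
                 record_dt: float = 1.0,
                 max_events: int = 2_000_000_000) -> list[Trajectory]:
    """Independent trajectories seeded ``base_seed + i``.

    Each run draws its own realization of the stimulus protocol, so results
    are independent of execution order (embarrassingly parallel contract).
    """
    from .stimulus import StimulusProtocol, realize
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(system, ReactionNetwork):
        system = compile_system(system)
    out = []
    for i in range(n_runs):
        run_seed = (int(base_seed) + i) % (1 << 31)
        if isinstance(protocol, StimulusProtocol):
            trace = realize(protocol, t_end, seed=(run_seed + 1_000_003) % (1 << 31))
        else:
            trace = protocol
        out.append(simulate(system, initial_counts, trace, t_end,
                            seed=run_seed, record_dt=record_dt,
                            max_events=max_events))
    return out
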