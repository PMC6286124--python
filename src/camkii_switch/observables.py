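"""Metrics computed from simulated trajectories.

Activity here always means the fraction of holoenzymes (rings) with at
least two phosphorylated subunits; rings bound in a PP1 complex count with
their current phospho-state.  The switch ON/OFF discretization is
hysteretic: the switch flips ON when activity reaches ``on_th`` and OFF when
it falls to ``off_th``, so chatter inside the intermediate band is not
counted as switching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .engine import Trajectory
from .rings import ACTIVE_THRESHOLD

__all__ = [
    "ActivityTrace", "SwitchStats", "SigmoidFit", "DecayFit", "SyncMetric",
    "RiseTimes", "activity_fraction", "switch_stats",
    "ring_intermediate_fraction", "pp1_tolerance_curve", "rise_times",
    "sync_strength", "occupancy_kl", "fit_decay", "mix_populations",
    "ensemble_decay", "active_count",
]

ON_THRESHOLD = 0.8
OFF_THRESHOLD = 0.2


# ---------------------------------------------------------------------------
# activity

@dataclass
class ActivityTrace:
    times: np.ndarray          # (T,)
    total: np.ndarray          # (T,) fraction of all rings active
    per_voxel: np.ndarray      # (T, n_voxels) fraction active per voxel
    n_rings: int
    n_rings_per_voxel: np.ndarray


def _ring_masks(traj: Trajectory):
    ring_like = np.array([s.kind in ("ring", "ring_complex")
                          for s in traj.species])
    active = np.array([s.kind in ("ring", "ring_complex")
                       and s.phospho_count >= ACTIVE_THRESHOLD
                       for s in traj.species])
    voxels = np.array([s.voxel for s in traj.species])
    return ring_like, active, voxels


def activity_fraction(traj: Trajectory) -> ActivityTrace:
    """Fraction of holoenzymes with >= 2 phosphorylated subunits."""
    ring_like, active, voxels = _ring_masks(traj)
    if not ring_like.any():
        raise ValueError("trajectory contains no ring species")
    n_vox = voxels.max() + 1
    total_rings = traj.counts[:, ring_like].sum(axis=1)
    if np.any(total_rings == 0):
        raise ValueError("no rings present at some record")
    total = traj.counts[:, active].sum(axis=1) / total_rings
    per_voxel = np.zeros((traj.counts.shape[0], n_vox))
    n_per_vox = np.zeros(n_vox, dtype=np.int64)
    for v in range(n_vox):
        in_v = voxels == v
        rings_v = traj.counts[:, ring_like & in_v].sum(axis=1)
        n_per_vox[v] = rings_v[0]
        with np.errstate(invalid="ignore"):
            per_voxel[:, v] = np.where(
                rings_v > 0,
                traj.counts[:, active & in_v].sum(axis=1) / np.maximum(rings_v, 1),
                np.nan)
    return ActivityTrace(traj.times, total, per_voxel,
                         int(total_rings[0]), n_per_vox)


def active_count(traj: Trajectory) -> np.ndarray:
    """Number of active holoenzymes at each record (for occupancy histograms)."""
    _, active, _ = _ring_masks(traj)
    return traj.counts[:, active].sum(axis=1)


def ring_intermediate_fraction(traj: Trajectory) -> float:
    """Time-average fraction of rings in intermediate states (2 < a < n-2)."""
    ring_like = np.array([s.kind in ("ring", "ring_complex")
                          for s in traj.species])
    inter = np.array([s.kind in ("ring", "ring_complex")
                      and 2 < s.a < s.n - 2 for s in traj.species])
    tot = traj.counts[:, ring_like].sum(axis=1)
    return float(np.mean(traj.counts[:, inter].sum(axis=1) / np.maximum(tot, 1)))


# ---------------------------------------------------------------------------
# switching statistics

@dataclass
class SwitchStats:
    residence_on: float
    residence_off: float
    relaxation_time: float
    n_transitions: int
    on_fraction: float
    censored: bool
    intermediate_fraction: float = float("nan")


def _discretize(values: np.ndarray, on_th: float, off_th: float) -> np.ndarray:
    """Hysteretic ON(1)/OFF(0) state per sample; -1 before first band entry."""
    state = np.full(values.size, -1, dtype=np.int8)
    cur = -1
    for i, v in enumerate(values):
        if v >= on_th:
            cur = 1
        elif v <= off_th:
            cur = 0
        state[i] = cur
    return state


def switch_stats(times: np.ndarray, values: np.ndarray,
                 on_th: float = ON_THRESHOLD,
                 off_th: float = OFF_THRESHOLD) -> SwitchStats:
    """Residence and relaxation times of the hysteretically discretized switch.

    Residence is the duration between consecutive flips (band entry to
    opposite-band entry); relaxation is the time spent crossing the
    intermediate band during a flip.  With no observed transition the
    residence times are censored at the trace length.
    """
    if not 0 <= off_th < on_th <= 1:
        raise ValueError("need 0 <= off_th < on_th <= 1")
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    state = _discretize(values, on_th, off_th)
    span = times[-1] - times[0]

    res = {0: [], 1: []}
    relax = []
    flips = 0
    cur = -1
    t_flip = None
    t_leave = None
    for i, s in enumerate(state):
        v = values[i]
        if cur == -1:
            if s != -1:
                cur, t_flip = s, times[i]
            continue
        in_band = (v >= on_th) if cur == 1 else (v <= off_th)
        opposite = (v <= off_th) if cur == 1 else (v >= on_th)
        if in_band:
            t_leave = None
        elif t_leave is None:
            t_leave = times[i]
        if opposite:
            res[cur].append(times[i] - t_flip)
            relax.append(times[i] - (t_leave if t_leave is not None else times[i]))
            cur, t_flip, t_leave = 1 - cur, times[i], None
            flips += 1

    censored = flips == 0
    r_on = float(np.mean(res[1])) if res[1] else span
    r_off = float(np.mean(res[0])) if res[0] else span
    rel = float(np.mean(relax)) if relax else 0.0
    classified = state >= 0
    on_frac = float(np.mean(state[classified] == 1)) if classified.any() else float("nan")
    return SwitchStats(r_on, r_off, rel, flips, on_frac, censored)


# ---------------------------------------------------------------------------
# PP1-tolerance sigmoid

@dataclass
class SigmoidFit:
    a: float
    k: float
    x0: float
    residual: float
    flagged: bool


def pp1_tolerance_curve(x: Sequence[float], on_fraction: Sequence[float]
                        ) -> SigmoidFit:
    """Least-squares fit of ON-time fraction vs x = N_PP1/N_CaMKII to
    a / (1 + exp(k (x - x0)))."""
    x = np.asarray(x, float)
    y = np.asarray(on_fraction, float)
    if x.size < 5:
        raise ValueError("need at least 5 grid points")
    if np.ptp(y) < 0.05:
        return SigmoidFit(float(np.mean(y)), 0.0, float("nan"),
                          float(np.std(y)), True)

    def f(x, a, k, x0):
        return a / (1.0 + np.exp(np.clip(k * (x - x0), -500, 500)))

    x0_guess = float(np.interp(0.5 * y.max(), y[::-1], x[::-1]))
    popt, _ = curve_fit(f, x, y, p0=[max(y.max(), 0.5), 1.0, x0_guess],
                        bounds=([0, 0, x.min() - np.ptp(x)],
                                [1.05, 100, x.max() + np.ptp(x)]),
                        maxfev=20000)
    resid = float(np.sqrt(np.mean((f(x, *popt) - y) ** 2)))
    return SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]),
                      resid, False)


# ---------------------------------------------------------------------------
# rise times

@dataclass
class RiseTimes:
    onset: float       # first crossing of 10% of max
    rise: float        # 10% -> 90% duration
    censored: bool


def rise_times(times: np.ndarray, values: np.ndarray,
               smooth_window: int = 11) -> RiseTimes:
    """Onset (0→10% of max) and rise (10%→90% of max) times of an
    activation trace, measured on a moving-average-smoothed copy."""
    times = np.asarray(times, float)
    v = np.asarray(values, float)
    if smooth_window > 1:
        kern = np.ones(smooth_window) / smooth_window
        v = np.convolve(v, kern, mode="same")
    vmax = v.max()
    if vmax <= 0:
        return RiseTimes(float("nan"), float("nan"), True)
    lo = np.nonzero(v >= 0.1 * vmax)[0]
    hi = np.nonzero(v >= 0.9 * vmax)[0]
    if lo.size == 0 or hi.size == 0:
        return RiseTimes(float("nan"), float("nan"), True)
    onset = float(times[lo[0]])
    return RiseTimes(onset, float(times[hi[0]] - times[lo[0]]), False)


# ---------------------------------------------------------------------------
# synchronization

@dataclass
class SyncMetric:
    ks: float          # synchronization strength, 1 - ti
    ti: float          # fraction of time clusters disagree

    #: synchronization counts as strong above this value
    STRONG: float = 0.4


def sync_strength(times: np.ndarray, per_cluster: np.ndarray,
                  on_th: float = ON_THRESHOLD,
                  off_th: float = OFF_THRESHOLD) -> SyncMetric:
    """Synchronization of clustered switches.

    Each cluster's activity is discretized hysteretically; ``ti`` is the
    fraction of time the clusters are not unanimous (neither all ON nor all
    OFF), and ks = 1 - ti.
    """
    per_cluster = np.asarray(per_cluster, float)
    if per_cluster.ndim != 2 or per_cluster.shape[1] < 2:
        raise ValueError("need >= 2 cluster activity traces")
    states = np.stack([_discretize(per_cluster[:, j], on_th, off_th)
                       for j in range(per_cluster.shape[1])], axis=1)
    defined = np.all(states >= 0, axis=1)
    if not defined.any():
        raise ValueError("no sample where every cluster is classified")
    s = states[defined]
    unanimous = np.all(s == 1, axis=1) | np.all(s == 0, axis=1)
    ti = float(1.0 - np.mean(unanimous))
    return SyncMetric(1.0 - ti, ti)


# ---------------------------------------------------------------------------
# occupancy histogram comparison

def occupancy_kl(test_hist: np.ndarray, ref_hist: np.ndarray,
                 alpha: float = 1.0) -> float:
    """Kullback-Leibler divergence D(test||ref) in bits between state
    occupancy histograms (counts over the same support), with additive
    smoothing of ``alpha`` counts per bin."""
    t = np.asarray(test_hist, float)
    r = np.asarray(ref_hist, float)
    if t.shape != r.shape:
        raise ValueError("histograms must share support")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    p = (t + alpha) / (t.sum() + alpha * t.size)
    q = (r + alpha) / (r.sum() + alpha * r.size)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


# ---------------------------------------------------------------------------
# decay fitting

@dataclass
class DecayFit:
    model: str
    tau: float = float("nan")
    P_fast: float = float("nan")
    tau_fast: float = float("nan")
    P_slow: float = float("nan")
    tau_slow: float = float("nan")
    stderr: tuple = ()
    flagged: bool = False


def fit_decay(times: np.ndarray, mean_act: np.ndarray, model: str = "single",
              fixed_weight: Optional[float] = None,
              floor_frac: Optional[float] = 0.02) -> DecayFit:
    """Nonlinear least-squares exponential fit of an ensemble-mean decay.

    The fit starts at the trace maximum (so a pulse-aligned trace that rises
    during the stimulus is fitted from its peak), and ``floor_frac``
    truncates the fit window where the trace first falls to that fraction of
    its peak value (the decay transient), so a long fully-decayed tail does
    not dominate the residuals.  The double model is
    A·(a·exp(-t/τ_fast) + (1-a)·exp(-t/τ_slow)) with the fast weight ``a``
    optionally fixed.
    """
    t = np.asarray(times, float)
    y = np.asarray(mean_act, float)
    i0 = int(np.argmax(y))
    if i0 < y.size - 4:
        t, y = t[i0:], y[i0:]
    t = t - t[0]
    if y[0] <= 0 or np.ptp(y) < 1e-3 * max(abs(y[0]), 1e-12):
        return DecayFit(model, flagged=True)
    if floor_frac is not None:
        below = np.nonzero(y <= floor_frac * y[0])[0]
        if below.size:
            cut = below[0] + 1
            if cut >= 5:
                t, y = t[:cut], y[:cut]
    if y.size < 4 or y[-1] >= y[0]:
        return DecayFit(model, flagged=True)

    if model == "single":
        def f(t, A, tau):
            return A * np.exp(-t / tau)
        tau0 = max(t[-1] / 3.0, t[1])
        popt, pcov = curve_fit(f, t, y, p0=[y[0], tau0],
                               bounds=([0, 1e-9], [np.inf, np.inf]),
                               maxfev=20000)
        err = tuple(np.sqrt(np.diag(pcov)))
        return DecayFit("single", tau=float(popt[1]), stderr=err)

    if model == "double":
        if fixed_weight is not None:
            if not 0 <= fixed_weight <= 1:
                raise ValueError("fixed_weight must be in [0, 1]")
            a = fixed_weight

            def f(t, A, tf, ts):
                return A * (a * np.exp(-t / tf) + (1 - a) * np.exp(-t / ts))

            popt, pcov = curve_fit(
                f, t, y, p0=[y[0], max(t[-1] / 20, t[1]), max(t[-1] / 2, t[1])],
                bounds=([0, 1e-9, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=50000)
            A, tf, ts = popt
            if tf > ts:
                tf, ts = ts, tf
                a_fast = 1 - a
            else:
                a_fast = a
            err = tuple(np.sqrt(np.diag(pcov)))
            return DecayFit("double", P_fast=float(a_fast), tau_fast=float(tf),
                            P_slow=float(1 - a_fast), tau_slow=float(ts),
                            stderr=err)

        def f(t, A, a, tf, ts):
            return A * (a * np.exp(-t / tf) + (1 - a) * np.exp(-t / ts))

        popt, pcov = curve_fit(
            f, t, y, p0=[y[0], 0.5, max(t[-1] / 20, t[1]), max(t[-1] / 2, t[1])],
            bounds=([0, 0, 1e-9, 1e-9], [np.inf, 1, np.inf, np.inf]),
            maxfev=50000)
        A, a, tf, ts = popt
        if tf > ts:
            tf, ts, a = ts, tf, 1 - a
        err = tuple(np.sqrt(np.diag(pcov)))
        return DecayFit("double", P_fast=float(a), tau_fast=float(tf),
                        P_slow=float(1 - a), tau_slow=float(ts), stderr=err)

    raise ValueError(f"unknown model {model!r}")


def mix_populations(fast_trace: np.ndarray, slow_trace: np.ndarray,
                    w_fast: float) -> np.ndarray:
    """Pointwise mixture w·fast + (1-w)·slow of two traces on a common grid."""
    f = np.asarray(fast_trace, float)
    s = np.asarray(slow_trace, float)
    if f.shape != s.shape:
        raise ValueError("traces must share a time grid")
    if not 0 <= w_fast <= 1:
        raise ValueError("w_fast must be in [0, 1]")
    return w_fast * f + (1.0 - w_fast) * s


# ---------------------------------------------------------------------------
# pulse-aligned ensemble decay

def ensemble_decay(trajectories: Sequence[Trajectory], period: float,
                   pulse_duration: float = 0.0, align: str = "onset"
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble- and pulse-averaged post-pulse activity decay.

    Segments every trajectory at each stimulus pulse (pulses start at
    t = k·period) and averages the aligned segments.  ``align="onset"``
    (default) puts t = 0 at the pulse onset, as the decay curves are
    presented; ``align="offset"`` starts at the pulse end instead.
    """
    if align not in ("onset", "offset"):
        raise ValueError("align must be 'onset' or 'offset'")
    segs = []
    for traj in trajectories:
        act = activity_fraction(traj)
        dt = act.times[1] - act.times[0]
        n_per = int(round(period / dt))
        i_off = int(round(pulse_duration / dt)) if align == "offset" else 0
        k = 0
        while (k * n_per + n_per) <= act.times.size:
            seg = act.total[k * n_per + i_off: (k + 1) * n_per]
            segs.append(seg)
            k += 1
    if not segs:
        raise ValueError("no complete pulse periods in the trajectories")
    n = min(len(s) for s in segs)
    stack = np.stack([s[:n] for s in segs])
    dt = trajectories[0].times[1] - trajectories[0].times[0]
    return np.arange(n) * dt, stack.mean(axis=0)
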