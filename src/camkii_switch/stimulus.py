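"""Piecewise-constant Ca2+ drive.

Basal synaptic Ca is modelled as an 80 nM resting level with stochastic
square fluctuations (the ε model): a 4 s period at 50% duty cycle whose
elevated half is drawn fresh each cycle from a uniform distribution of
median 120 nM and width 40 nM.  Strong stimuli are periodic square pulses.
Ca has no decay kinetics and is spatially uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Segment", "StimulusProtocol", "CaTrace",
           "basal_protocol", "pulse_protocol", "realize"]


@dataclass(frozen=True)
class Segment:
    """One protocol segment: fixed level, or a fresh uniform draw per cycle."""

    duration: float               # s
    level: float                  # µM (median for uniform rule)
    width: float = 0.0            # full uniform range, µM; 0 = fixed level

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.width < 0:
            raise ValueError("uniform width must be >= 0")
        if self.level - self.width / 2 <= 0:
            raise ValueError("Ca levels must stay > 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered segments repeated periodically."""

    segments: tuple[Segment, ...]

    @property
    def period(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class CaTrace:
    """Piecewise-constant Ca trace: level[i] holds on [breakpoints[i], breakpoints[i+1])."""

    breakpoints: np.ndarray   # shape (k+1,), strictly increasing, covers [0, t_end]
    levels: np.ndarray        # shape (k,), µM

    def __post_init__(self) -> None:
        bp, lv = np.asarray(self.breakpoints, float), np.asarray(self.levels, float)
        if bp.ndim != 1 or lv.ndim != 1 or bp.size != lv.size + 1:
            raise ValueError("need len(breakpoints) == len(levels) + 1")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(lv <= 0):
            raise ValueError("Ca levels must be > 0")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)

    @property
    def t_end(self) -> float:
        return float(self.breakpoints[-1])

    def at(self, t: float) -> float:
        """Ca level at time t (right-open intervals)."""
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return float(self.levels[min(max(i, 0), self.levels.size - 1)])

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"time_s": self.breakpoints[:-1],
                      "ca_uM": self.levels}).to_csv(path, index=False)


def basal_protocol(baseline: float = 0.080, *, elevated_median: Optional[float] = None,
                   elevated_width: float = 0.040, period: float = 4.0,
                   duty: float = 0.5) -> StimulusProtocol:
    """Background activity: baseline alternating with fluctuating elevations.

    Each cycle spends ``duty`` of the period at the baseline and the rest at
    an independent uniform draw centred on ``elevated_median`` (default
    baseline + 40 nM, which for the standard 80 nM baseline is the published
    Uniform[100, 140] nM distribution).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if not 0 < duty < 1:
        raise ValueError("duty must be in (0, 1)")
    if elevated_median is None:
        elevated_median = baseline + 0.040
    return StimulusProtocol((
        Segment(period * duty, baseline),
        Segment(period * (1 - duty), elevated_median, elevated_width),
    ))


def pulse_protocol(pulse_level: float, pulse_duration: float, period: float,
                   baseline: float = 0.080) -> StimulusProtocol:
    """Strong periodic pulse: pulse_level for pulse_duration, baseline otherwise."""
    if pulse_duration >= period:
        raise ValueError("pulse_duration must be < period")
    return StimulusProtocol((
        Segment(pulse_duration, pulse_level),
        Segment(period - pulse_duration, baseline),
    ))


def realize(protocol: StimulusProtocol, t_end: float, seed: int) -> CaTrace:
    """Sample a concrete trace on [0, t_end]; pure given (protocol, t_end, seed)."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    rng = np.random.default_rng(seed)
    times, levels = [0.0], []
    t = 0.0
    while t < t_end:
        for seg in protocol.segments:
            if seg.width > 0:
                lv = rng.uniform(seg.level - seg.width / 2,
                                 seg.level + seg.width / 2)
            else:
                lv = seg.level
            t += seg.duration
            levels.append(lv)
            times.append(t)
            if t >= t_end:
                break
    bp = np.array(times)
    bp[-1] = t_end  # truncate the final segment at t_end
    return CaTrace(bp, np.array(levels))
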