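"""CaMKII ring phospho-states.

A CaMKII holoenzyme is two stacked rings of 6 or 7 subunits; vertical dimers
phosphorylate together, so the ring stands in for the holoenzyme and a ring
"subunit" for a vertical dimer.  Phosphorylated subunits form a single
contiguous block (discontiguous arrangements are kinetically negligible), so
a ring state is fully determined by its size ``n`` and its number of
unphosphorylated subunits ``a``.  Over n in {6, 7} there are exactly 15
distinct states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["RingState", "enumerate_states", "is_active"]

#: Minimum number of phosphorylated subunits for a holoenzyme to count as active.
ACTIVE_THRESHOLD = 2


@dataclass(frozen=True, order=True)
class RingState:
    """One ring's phospho-configuration.

    Parameters
    ----------
    n : int
        Subunits per ring (6 or 7 in the physiological model).
    a : int
        Number of unphosphorylated subunits, ``0 <= a <= n``.
    """

    n: int
    a: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"ring size must be >= 1, got {self.n}")
        if not 0 <= self.a <= self.n:
            raise ValueError(f"need 0 <= a <= n, got a={self.a}, n={self.n}")

    @property
    def phospho(self) -> int:
        """Number of phosphorylated subunits (n - a)."""
        return self.n - self.a

    @property
    def label(self) -> str:
        """Canonical label ``x{a}y{n-a}``, used in all trajectory output."""
        return f"x{self.a}y{self.n - self.a}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_states(ring_sizes: Iterable[int]) -> list[RingState]:
    """All ring states for the given ring sizes.

    Returns states in deterministic order: ascending ``n``, then ascending
    ``a``.  For sizes {6, 7} this yields the model's 15 states.
    """
    sizes = sorted(set(ring_sizes))
    if not sizes:
        raise ValueError("ring_sizes must not be empty")
    if any(n < 1 for n in sizes):
        raise ValueError(f"every ring size must be >= 1, got {sizes}")
    return [RingState(n, a) for n in sizes for a in range(n + 1)]


def is_active(state: RingState) -> bool:
    """Whether a ring counts as active: at least two phosphorylated subunits."""
    return state.phospho >= ACTIVE_THRESHOLD
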