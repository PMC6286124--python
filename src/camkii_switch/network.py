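"""Stochastic reaction network for the CaMKII/PP1 pathway.

Generates the full reaction set for a given parameter set and compartment
volume, with propensities in molecule-count units:

* autophosphorylation of ring subunits, Ca-dependent (slow initiation v1 of a
  fully unphosphorylated ring, fast propagation v2 otherwise),
* dephosphorylation by PP1 through an explicit enzyme-substrate complex
  (association k+, catalysis k2, dissociation k- = 0 by default), for both
  ring-bound and free phosphorylated subunits,
* subunit exchange: hexamers gain a free subunit to become heptamers,
  heptamers lose one to become hexamers,
* PP1 sequestration by phosphorylated inhibitor-1 (I1P), with I1P treated as
  an algebraic function of Ca rather than a counted species,
* slow turnover replacing any phosphorylated ring by a fresh one.

Second-order propensities are per reactant pair: c = k_assoc / (N_A · V),
with N_A · 1 µM · 1 µm³ = 602.2 molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import N_AVOGADRO_UM3, Parameters, SystemConfig
from .rings import RingState, enumerate_states

__all__ = [
    "Species", "Reaction", "ReactionNetwork",
    "phospho_rates", "i1p_level",
    "build_phospho_reactions", "build_dephospho_reactions",
    "build_exchange_reactions", "build_pp1_inhibition_reactions",
    "build_turnover_reactions", "assemble_network",
]

RING_SIZES = (6, 7)

# Ca-dependent rate laws understood by the simulation engines.
CA_LAWS = ("v1", "v2", "i1p_assoc")


# ---------------------------------------------------------------------------
# rate laws

def phospho_rates(ca: float, p: Parameters) -> tuple[float, float]:
    """Initiation (v1) and propagation (v2) phosphorylation rates at [Ca2+] = ca µM.

    v2 = k1 * H^nH1 / (1 + H^nH1) with H = Ca/KH1; initiation requires two
    simultaneous Ca/CaM bindings, so v1 = k1 * (H^nH1/(1+H^nH1))^2 = v2^2/k1.
    """
    if ca < 0:
        raise ValueError(f"ca must be >= 0, got {ca}")
    h = (ca / p.KH1) ** p.nH1
    sat = h / (1.0 + h)
    v2 = p.k1 * sat
    v1 = p.k1 * sat * sat
    return v1, v2


def i1p_level(ca: float, p: Parameters) -> float:
    """Concentration (µM) of phosphorylated inhibitor-1 at [Ca2+] = ca µM.

    I1P is set algebraically by the PKA/calcineurin balance.  Two readings of
    the published expression are supported via ``p.i1p_mode``:

    * ``"increasing"`` (default): I1P = I1·(vPKA/vCaN)·H^n/(1+H^n), rising
      with Ca toward I1·vPKA/vCaN.  Under this reading PP1 is partially free
      at basal Ca and sequestered during strong Ca input, which is the regime
      in which the switch and the spine integrator operate.
    * ``"decreasing"``: I1P = I1·(vPKA/vCaN)·(1+H^n)/H^n, diverging as
      Ca → 0 and falling toward I1·vPKA/vCaN.
    """
    if ca < 0:
        raise ValueError(f"ca must be >= 0, got {ca}")
    scale = p.I1 * p.vPKA_over_vCaN
    if p.i1p_mode == "decreasing":
        if ca == 0:
            raise ValueError("i1p_level diverges at ca=0 in decreasing mode")
        h = (ca / p.KH2) ** p.nH2
        return scale * (1.0 + h) / h
    h = (ca / p.KH2) ** p.nH2
    return scale * h / (1.0 + h)


# ---------------------------------------------------------------------------
# species / reactions

@dataclass(frozen=True)
class Species:
    """A counted molecular species.

    ``kind`` is one of ``ring``, ``ring_complex`` (PP1-bound ring),
    ``free_subunit``, ``pp1``, ``pp1_i1p``, ``pp1_subunit``.  Ring-like
    species carry (n, a); free subunits carry ``phospho`` in {0, 1}.
    """

    name: str
    kind: str
    n: int = 0
    a: int = 0
    phospho_count: int = 0     # phosphorylated subunits carried
    subunit_weight: int = 0    # CaMKII subunits carried (conservation)
    pp1_weight: int = 0        # PP1 molecules carried (conservation)
    diffusible: bool = False
    voxel: int = 0             # voxel index in a spatialized network
    local_name: str = ""       # species name without the voxel prefix

    def __post_init__(self) -> None:
        if not self.local_name:
            object.__setattr__(self, "local_name", self.name)


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction channel.

    ``rate`` is the stochastic rate constant: s^-1 for first order, per-pair
    s^-1 for second order (already volume-converted).  If ``ca_law`` is set,
    the propensity is multiplied by the law value at the current Ca (and
    ``rate`` acts as a dimensionless scale, normally 1).
    """

    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: float
    ca_law: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"negative rate in {self.name}")
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError(f"reaction {self.name} must have 1 or 2 reactants")
        if self.ca_law is not None and self.ca_law not in CA_LAWS:
            raise ValueError(f"unknown ca_law {self.ca_law!r}")

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __str__(self) -> str:
        lhs = " + ".join(self.reactants)
        rhs = " + ".join(self.products) if self.products else "∅"
        law = f" × {self.ca_law}(Ca)" if self.ca_law else ""
        return f"{lhs} -> {rhs}  @ {self.rate:.4g}{law}"


def ring_species(state: RingState) -> Species:
    return Species(state.label, "ring", n=state.n, a=state.a,
                   phospho_count=state.phospho, subunit_weight=state.n)


def complex_species(state: RingState) -> Species:
    return Species(f"PP1_{state.label}", "ring_complex", n=state.n, a=state.a,
                   phospho_count=state.phospho, subunit_weight=state.n,
                   pp1_weight=1)


def _base_species(with_exchange: bool) -> list[Species]:
    sp: list[Species] = [ring_species(s) for s in enumerate_states(RING_SIZES)]
    sp += [complex_species(s) for s in enumerate_states(RING_SIZES) if s.a < s.n]
    sp.append(Species("PP1", "pp1", pp1_weight=1, diffusible=True))
    sp.append(Species("PP1_I1P", "pp1_i1p", pp1_weight=1))
    if with_exchange:
        sp.append(Species("x", "free_subunit", subunit_weight=1, diffusible=True))
        sp.append(Species("y", "free_subunit", phospho_count=1,
                          subunit_weight=1, diffusible=True))
        sp.append(Species("PP1_y", "pp1_subunit", phospho_count=1,
                          subunit_weight=1, pp1_weight=1))
    return sp


# ---------------------------------------------------------------------------
# reaction builders

def build_phospho_reactions(p: Parameters) -> list[Reaction]:
    """Ca-driven subunit phosphorylation: initiation (v1) then propagation (v2)."""
    out = []
    for n in RING_SIZES:
        for a in range(1, n + 1):
            law = "v1" if a == n else "v2"
            out.append(Reaction(
                f"phospho_{law}_x{a}y{n - a}",
                (RingState(n, a).label,), (RingState(n, a - 1).label,),
                rate=1.0, ca_law=law))
    return out


def build_dephospho_reactions(p: Parameters, volume: float) -> list[Reaction]:
    """PP1-mediated dephosphorylation through explicit complexes.

    Includes the free-subunit branch PP1 + y ⇌ PP1·y → PP1 + x (only
    meaningful when exchange species exist; harmlessly unused otherwise).
    """
    c_assoc = p.kplus / (N_AVOGADRO_UM3 * volume)
    out = []
    for n in RING_SIZES:
        for a in range(0, n):
            st, up = RingState(n, a), RingState(n, a + 1)
            cx = f"PP1_{st.label}"
            out.append(Reaction(f"pp1_bind_{st.label}", ("PP1", st.label), (cx,),
                                rate=c_assoc))
            out.append(Reaction(f"pp1_cat_{st.label}", (cx,), ("PP1", up.label),
                                rate=p.k2))
            if p.kminus > 0:
                out.append(Reaction(f"pp1_unbind_{st.label}", (cx,),
                                    ("PP1", st.label), rate=p.kminus))
    out.append(Reaction("pp1_bind_y", ("PP1", "y"), ("PP1_y",), rate=c_assoc))
    out.append(Reaction("pp1_cat_y", ("PP1_y",), ("PP1", "x"), rate=p.k2))
    if p.kminus > 0:
        out.append(Reaction("pp1_unbind_y", ("PP1_y",), ("PP1", "y"),
                            rate=p.kminus))
    return out


def build_exchange_reactions(p: Parameters, cfg: SystemConfig,
                             volume_fraction: float = 1.0) -> list[Reaction]:
    """Subunit gain/loss (exchange).

    Hexamers gain a free subunit to become heptamers; heptamers lose one
    (rate kx_loss for x, ky_loss for y) to become hexamers.  The gain rate
    scale is "kx_gain s^-1 per N_CaMKII": the per-pair propensity is
    kx_gain / (N_CaMKII · volume_fraction), so that a single free subunit in
    a uniformly populated system is taken up at kx_gain s^-1 in total,
    independent of volume and voxelization.  ``volume_fraction`` is this
    compartment's share of the total system volume.
    """
    if volume_fraction <= 0:
        raise ValueError("volume_fraction must be > 0")
    n_ref = max(cfg.N_CaMKII, 1)
    c_gx = p.kx_gain / (n_ref * volume_fraction)
    c_gy = p.ky_gain / (n_ref * volume_fraction)
    out = []
    for a in range(0, 7):  # hexamer states x_a y_{6-a}
        hexa = RingState(6, a)
        out.append(Reaction(f"gain_x_{hexa.label}", (hexa.label, "x"),
                            (RingState(7, a + 1).label,), rate=c_gx))
        out.append(Reaction(f"gain_y_{hexa.label}", (hexa.label, "y"),
                            (RingState(7, a).label,), rate=c_gy))
    for a in range(0, 8):  # heptamer states x_a y_{7-a}
        hept = RingState(7, a)
        if a >= 1:
            out.append(Reaction(f"lose_x_{hept.label}", (hept.label,),
                                (RingState(6, a - 1).label, "x"), rate=p.kx_loss))
        if 7 - a >= 1:
            out.append(Reaction(f"lose_y_{hept.label}", (hept.label,),
                                (RingState(6, a).label, "y"), rate=p.ky_loss))
    return out


def build_pp1_inhibition_reactions(p: Parameters) -> list[Reaction]:
    """PP1 sequestration by I1P, pseudo-first-order in PP1.

    I1P is an algebraic Ca-dependent concentration, so association is a
    Ca-law channel with rate k3·[I1P](Ca); dissociation is constant k4.
    """
    return [
        Reaction("pp1_i1p_bind", ("PP1",), ("PP1_I1P",), rate=1.0,
                 ca_law="i1p_assoc"),
        Reaction("pp1_i1p_unbind", ("PP1_I1P",), ("PP1",), rate=p.k4),
    ]


def build_turnover_reactions(p: Parameters) -> list[Reaction]:
    """Constant-rate replacement of any phosphorylated ring by a fresh one."""
    if p.vt == 0:
        return []
    out = []
    for n in RING_SIZES:
        for a in range(0, n):
            out.append(Reaction(f"turnover_x{a}y{n - a}",
                                (RingState(n, a).label,),
                                (RingState(n, n).label,), rate=p.vt))
    return out


# ---------------------------------------------------------------------------
# network container

@dataclass
class ReactionNetwork:
    """Species list plus reaction channels, with conservation checking."""

    species: list[Species]
    reactions: list[Reaction]
    params: Parameters
    volume: float
    with_exchange: bool = True

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")
        for r in self.reactions:
            for name in r.reactants + r.products:
                if name not in self._index:
                    raise ValueError(f"reaction {r.name} references unknown "
                                     f"species {name!r}")
        self.check_conservation()

    def species_index(self, name: str) -> int:
        return self._index[name]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def stoichiometry(self) -> np.ndarray:
        """Dense stoichiometry matrix, shape (n_species, n_reactions)."""
        S = np.zeros((len(self.species), len(self.reactions)), dtype=np.int64)
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                S[self._index[name], j] -= 1
            for name in r.products:
                S[self._index[name], j] += 1
        return S

    def conserved_weights(self) -> dict[str, np.ndarray]:
        sub = np.array([s.subunit_weight for s in self.species], dtype=np.int64)
        pp1 = np.array([s.pp1_weight for s in self.species], dtype=np.int64)
        return {"subunits": sub, "pp1": pp1}

    def check_conservation(self) -> None:
        """Every reaction must conserve total subunits and total PP1."""
        S = self.stoichiometry()
        for qty, w in self.conserved_weights().items():
            bad = np.nonzero(w @ S)[0]
            if bad.size:
                raise ValueError(
                    f"reactions violate {qty} conservation: "
                    + ", ".join(self.reactions[j].name for j in bad[:5]))

    def to_table(self) -> str:
        """Human-readable reaction table for audit."""
        lines = [f"{'reaction':<22} {'channel':<55} order"]
        for r in self.reactions:
            lines.append(f"{r.name:<22} {str(r):<55} {r.order}")
        return "\n".join(lines)

    def ode_rhs(self, ca: Optional[float] = None):
        """Deterministic mass-action right-hand side f(t, counts).

        Counts-space ODE using the same stochastic rate constants as the SSA
        (per-pair second-order rates), hence directly comparable to ensemble
        means.  ``ca`` fixes the Ca level for Ca-law channels (required if
        any are present).
        """
        laws = {r.ca_law for r in self.reactions if r.ca_law}
        if laws and ca is None:
            raise ValueError("network has Ca-dependent channels; pass ca")
        g = {}
        if ca is not None:
            v1, v2 = phospho_rates(ca, self.params)
            g = {"v1": v1, "v2": v2,
                 "i1p_assoc": self.params.k3 * i1p_level(ca, self.params)}
        S = self.stoichiometry().astype(float)
        rates = np.array([r.rate * (g[r.ca_law] if r.ca_law else 1.0)
                          for r in self.reactions])
        ri = np.array([self._index[r.reactants[0]] for r in self.reactions])
        rj = np.array([self._index[r.reactants[1]] if r.order == 2 else -1
                       for r in self.reactions])
        second = rj >= 0

        def rhs(t: float, nvec: np.ndarray) -> np.ndarray:
            a = rates * nvec[ri]
            a[second] *= nvec[rj[second]]
            return S @ a

        return rhs


def assemble_network(p: Parameters, cfg: SystemConfig, with_exchange: bool = True,
                     volume: Optional[float] = None,
                     volume_fraction: float = 1.0) -> ReactionNetwork:
    """Full network for one well-mixed compartment.

    ``volume`` defaults to ``cfg.volume``; pass the per-voxel volume (and the
    matching ``volume_fraction``) when building a voxelized system.  With
    ``with_exchange=False`` the exchange reactions and free-subunit species
    are omitted entirely.
    """
    if volume is None:
        volume = cfg.volume
    if volume <= 0:
        raise ValueError("volume must be > 0")
    species = _base_species(with_exchange)
    known = {s.name for s in species}
    reactions = build_phospho_reactions(p)
    reactions += [r for r in build_dephospho_reactions(p, volume)
                  if set(r.reactants) | set(r.products) <= known]
    if with_exchange:
        reactions += build_exchange_reactions(p, cfg, volume_fraction)
    reactions += build_pp1_inhibition_reactions(p)
    reactions += build_turnover_reactions(p)
    return ReactionNetwork(species, reactions, p, volume, with_exchange)
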