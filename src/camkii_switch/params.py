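"""Model parameters and system configuration.

Defaults follow the published parameter table of the extended CaMKII/PP1
model: Hill-type Ca activation of autophosphorylation, mass-action PP1
kinetics, inhibitor-1 regulation of PP1, slow turnover, and subunit-exchange
gain/loss rates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

__all__ = ["Parameters", "SystemConfig", "N_AVOGADRO_UM3"]

#: molecules per (µM · µm³): N_A * 1e-6 mol/L * 1e-15 L/µm³
N_AVOGADRO_UM3 = 602.2


@dataclass
class Parameters:
    """Rate parameters of the CaMKII/PP1 network.

    All first-order rates in s^-1, association rates in µM^-1 s^-1,
    concentrations in µM.
    """

    k1: float = 1.5          # autophosphorylation catalytic constant
    KH1: float = 0.7         # Hill constant, Ca activation of CaMKII
    nH1: float = 3.0         # Hill exponent, Ca activation
    KH2: float = 0.3         # Hill constant, Ca control of I1P
    nH2: float = 3.0         # Hill exponent, I1P
    k2: float = 1.0          # PP1 catalytic constant
    KM: float = 10.0         # PP1 Michaelis constant
    kplus: float = 1.0       # PP1-ring/subunit association (see note below)
    kminus: float = 0.0      # PP1-ring dissociation (assumed 0)
    k3: float = 100.0        # I1P.PP1 association
    k4: float = 0.1          # I1P.PP1 dissociation
    I1: float = 10.0         # free inhibitor-1 concentration
    vPKA_over_vCaN: float = 1.0
    vt: float = 1.0 / (30.0 * 3600.0)  # turnover: once per 30 h
    kx_gain: float = 1.0     # subunit gain rate scale (s^-1 per N_CaMKII)
    ky_gain: float = 1.0
    kx_loss: float = 0.1     # subunit loss rate (per heptamer)
    ky_loss: float = 0.1
    # "increasing": I1P = I1*r*H^n/(1+H^n) (rises with Ca toward I1*r);
    # "decreasing": I1P = I1*r*(1+H^n)/H^n (falls with Ca toward I1*r).
    # The increasing mode is the default: it is the only reading under which
    # PP1 is appreciably active at basal Ca, as the model's dynamics require.
    i1p_mode: str = "increasing"

    # kplus: the model text fixes k+ = k2/KM and states the value 1 /µM/s,
    # although k2/KM with the table values is 0.1.  The value 1 also uniquely
    # reproduces the published h_crit <= 3.2 nm bound, so it is the default;
    # it remains an ordinary config parameter.

    def __post_init__(self) -> None:
        for name in ("k1", "KH1", "nH1", "KH2", "nH2", "k2", "KM", "kplus",
                     "kminus", "k3", "k4", "I1", "vPKA_over_vCaN", "vt",
                     "kx_gain", "ky_gain", "kx_loss", "ky_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be >= 0")
        if self.i1p_mode not in ("increasing", "decreasing"):
            raise ValueError(f"unknown i1p_mode {self.i1p_mode!r}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Parameters":
        return cls(**d)

    def replace(self, **kwargs: Any) -> "Parameters":
        d = self.to_dict()
        d.update(kwargs)
        return Parameters.from_dict(d)


@dataclass
class SystemConfig:
    """Population and compartment configuration.

    Parameters
    ----------
    N_CaMKII : int
        Total holoenzymes (rings) in the system.
    N_PP1 : int
        Total PP1 molecules.
    volume : float
        Compartment volume in µm³.
    hexamer_fraction : float
        Fraction of rings that are hexamers at t=0 (the rest heptamers).
    initial_phospho : str
        ``"off"`` (all x_n y_0) or ``"on"`` (all x_0 y_n).
    """

    N_CaMKII: int = 12
    N_PP1: int = 60
    volume: float = 0.0275
    hexamer_fraction: float = 0.5
    initial_phospho: str = "off"

    def __post_init__(self) -> None:
        if self.N_CaMKII < 0 or self.N_PP1 < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if not 0.0 <= self.hexamer_fraction <= 1.0:
            raise ValueError("hexamer_fraction must be in [0, 1]")
        if self.initial_phospho not in ("off", "on"):
            raise ValueError("initial_phospho must be 'off' or 'on'")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SystemConfig":
        return cls(**d)
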