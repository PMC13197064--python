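"""Rate laws and mass balances of the extracellular levan-synthesis model.

The batch-fermentation model tracks seven states: biomass X (gDW/L),
secreted levansucrase E (mg/L), the cumulative sucrose routed into growth
S_cell (mM), and the extracellular pools glucose, fructose, reactor
sucrose, and levan (all mM; levan in fructosyl-monomer equivalents).

Growth follows Monod kinetics on reactor sucrose with first-order death.
Levansucrase is growth-associated: it accumulates at rate ``alpha * mu * X``
(yield alpha, mg enzyme per gDW biomass).  The secreted enzyme catalyses
three reactions, expressed as specific activities (mmol per mg enzyme per
hour) and scaled by the active enzyme pool ``E_pool = alpha * X``:

* hydrolysis (v3): sucrose -> glucose + fructose, single-substrate
  Michaelis-Menten;
* transfructosylation (v4): sucrose (+ optionally free fructose as an
  acceptor) -> levan + glucose, a two-term saturable rate;
* levan degradation (v5): levan -> fructose, gated by a Heaviside switch
  at ``t_levdeg_onset`` and acting on the degradable 67% of the polymer.

The mass balances deliberately reproduce the source model's bookkeeping,
including its fructosyl non-conservation in the transfructosylation step
(one sucrose plus one free fructose yield a single levan unit plus
glucose); see ``docs/methods.md``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Literal

import numpy as np

__all__ = [
    "KineticParameterSet",
    "FermentationState",
    "RateVector",
    "STATE_NAMES",
    "growth_rate",
    "hydrolysis_rate",
    "transfructosylation_rate",
    "levan_degradation_rate",
    "rates",
    "rhs",
]

#: order of the state vector used by the integrator
STATE_NAMES = ("X", "E", "S_cell", "Glc", "Fru", "S_reactor", "Levan")

EquationVariant = Literal["enzyme_pool", "as_printed"]


@dataclass(frozen=True)
class KineticParameterSet:
    """All rate-law constants for one sucrose regime.

    Units: mu_max, kd in 1/h; Ks and every K_M in mM (KM_trans2 in mM^2,
    consistent with the fructose*sucrose product it divides); Y_XS in
    gDW/mmol sucrose; alpha in mg enzyme/gDW; vmax_* in mmol/(mg enzyme h);
    t_levdeg_onset in h.
    """

    mu_max: float
    Ks: float
    kd: float
    Y_XS: float
    alpha: float
    vmax_hyd: float
    KM_hyd: float
    vmax_trans1: float
    KM_trans1: float
    vmax_trans2: float
    KM_trans2: float
    vmax_levdeg: float
    KM_levdeg: float
    t_levdeg_onset: float
    #: non-degradable share of the levan pool (the rate law sees 1-this of levan)
    degradable_fraction_complement: float = 0.33
    regime_label: str = "custom"

    def __post_init__(self):
        nonneg = (
            "mu_max kd alpha vmax_hyd vmax_trans1 vmax_trans2 "
            "vmax_levdeg t_levdeg_onset"
        ).split()
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("Ks", "KM_hyd", "KM_trans1", "KM_trans2", "KM_levdeg", "Y_XS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.degradable_fraction_complement < 1.0:
            raise ValueError("degradable_fraction_complement must lie in [0, 1)")

    def with_updates(self, **changes) -> "KineticParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameterSet":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "KineticParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FermentationState:
    """One snapshot of the batch culture (mM except X in gDW/L, E in mg/L)."""

    X: float
    E: float
    S_cell: float
    Glc: float
    Fru: float
    S_reactor: float
    Levan: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.X, self.E, self.S_cell, self.Glc, self.Fru, self.S_reactor, self.Levan]
        )

    @classmethod
    def from_array(cls, y, t: float = 0.0) -> "FermentationState":
        return cls(*map(float, y), t=t)


@dataclass(frozen=True)
class RateVector:
    """Instantaneous rates: mu (1/h), v1 (mmol/(L h)), v2 (mg/(L h)),
    v3-v5 specific (mmol/(mg h)) plus their volumetric equivalents after
    multiplication by the enzyme pool (mmol/(L h))."""

    mu: float
    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    v3_vol: float
    v4_vol: float
    v5_vol: float


def _require_nonneg(value, name):
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError(f"{name} must be non-negative")
    return value


def growth_rate(p: KineticParameterSet, S_reactor):
    """Monod specific growth rate mu = mu_max * S / (Ks + S), 1/h."""
    S = _require_nonneg(S_reactor, "S_reactor")
    return p.mu_max * S / (p.Ks + S)


def hydrolysis_rate(p: KineticParameterSet, S_reactor):
    """Specific sucrose hydrolysis rate, mmol/(mg enzyme h)."""
    S = _require_nonneg(S_reactor, "S_reactor")
    return p.vmax_hyd * S / (p.KM_hyd + S)


def transfructosylation_rate(p: KineticParameterSet, S_reactor, Fru):
    """Specific transfructosylation rate, mmol/(mg enzyme h).

    Two-term saturable law: a sucrose-only route and a fructose-acceptor
    route sharing one denominator,
    ``(v1*S/K1 + v2*F*S/K2) / (1 + S/K1 + F*S/K2)``.
    """
    S = _require_nonneg(S_reactor, "S_reactor")
    F = _require_nonneg(Fru, "Fru")
    a = S / p.KM_trans1
    b = F * S / p.KM_trans2
    return (p.vmax_trans1 * a + p.vmax_trans2 * b) / (1.0 + a + b)


def levan_degradation_rate(p: KineticParameterSet, Levan, t):
    """Specific levan degradation rate, mmol/(mg enzyme h).

    Acts only after ``t_levdeg_onset`` and only on the degradable fraction
    of the polymer (``(1 - 0.33) * Levan`` by default).
    """
    L = _require_nonneg(Levan, "Levan")
    gate = np.where(np.asarray(t, dtype=float) >= p.t_levdeg_onset, 1.0, 0.0)
    L_eff = (1.0 - p.degradable_fraction_complement) * L
    return gate * p.vmax_levdeg * L_eff / (p.KM_levdeg + L_eff)


def rates(state: FermentationState, p: KineticParameterSet, t: float | None = None) -> RateVector:
    """Evaluate all instantaneous rates at a state."""
    if t is None:
        t = state.t
    mu = float(growth_rate(p, state.S_reactor))
    v1 = mu * state.X / p.Y_XS
    v2 = p.alpha * mu * state.X
    v3 = float(hydrolysis_rate(p, state.S_reactor))
    v4 = float(transfructosylation_rate(p, state.S_reactor, state.Fru))
    v5 = float(levan_degradation_rate(p, state.Levan, t))
    e_pool = p.alpha * state.X
    return RateVector(
        mu=mu, v1=v1, v2=v2, v3=v3, v4=v4, v5=v5,
        v3_vol=v3 * e_pool, v4_vol=v4 * e_pool, v5_vol=v5 * e_pool,
    )


def rhs(
    state: FermentationState,
    p: KineticParameterSet,
    t: float | None = None,
    equations: EquationVariant = "enzyme_pool",
) -> tuple[np.ndarray, RateVector]:
    """Time derivative of the state vector (order ``STATE_NAMES``).

    ``equations='enzyme_pool'`` (default) multiplies all three specific
    enzymatic rates by the enzyme pool ``alpha*X`` so every volumetric flux
    carries mmol/(L h).  ``'as_printed'`` leaves v3 bare in the glucose,
    fructose and reactor-sucrose balances, reproducing the source text
    literally for comparison.

    S_cell accumulates the sucrose routed into growth (positive cumulative
    integral of v1).
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state")
    rv = rates(state, p, t)
    e_pool = p.alpha * state.X
    v5g = rv.v5  # already gated by the Heaviside factor inside the rate law
    if equations == "enzyme_pool":
        dGlc = (rv.v3 + rv.v4) * e_pool
        dFru = (rv.v3 - rv.v4 + v5g) * e_pool
        dLev = (rv.v4 - v5g) * e_pool
        dSr = -rv.v1 - (rv.v3 + rv.v4) * e_pool
    elif equations == "as_printed":
        dGlc = rv.v3 + rv.v4 * e_pool
        dFru = rv.v3 + (-rv.v4 + v5g) * e_pool
        dLev = (rv.v4 - v5g) * e_pool
        dSr = -rv.v1 - rv.v3 - rv.v4 * e_pool
    else:  # pragma: no cover - guarded typo
        raise ValueError(f"unknown equation variant {equations!r}")
    # order: X, E, S_cell, Glc, Fru, S_reactor, Levan (STATE_NAMES)
    dy = np.array([
        (rv.mu - p.kd) * state.X,
        rv.v2,
        rv.v1,  # cumulative sucrose routed to growth
        dGlc,
        dFru,
        dSr,
        dLev,
    ])
    return dy, rv
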