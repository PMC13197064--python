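"""Constraint-based (stoichiometric) side of the hybrid model.

The kinetic model supplies three snapshot constraints — the Monod growth
rate, the sucrose uptake rate mu/Y_XS, and the levansucrase yield alpha —
which are imposed on a stoichiometric network as fixed fluxes (growth,
uptake, and enzyme synthesis at ``alpha * mu / MW``).  The constrained
network is then solved for the minimal-total-flux distribution (all
reactions split into irreversible pairs, minimise the summed flux subject
to steady state), and per-metabolite turnover is summarised as flux-sums
normalised by the sucrose uptake rate.  Reactions are classified as
active/inactive per condition at a 1e-6 mmol/(gDW h) threshold.

SBML L3+FBC input/output is delegated to cobrapy; the LP itself is solved
with scipy's HiGHS interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "StoichModel", "CouplingConstraints", "FluxSolution",
    "load_stoich_model", "save_stoich_model", "augment_levansucrase",
    "remove_levansucrase", "apply_coupling", "solve_min_total_flux",
    "solve_fba", "flux_sum", "classify_activity",
    "LEVANSUCRASE_MW", "ACTIVITY_THRESHOLD",
]

#: SacB-class protein molecular weight, mg/mmol (config-overridable)
LEVANSUCRASE_MW = 53_000.0
#: |flux| below this (mmol/(gDW h)) counts as inactive
ACTIVITY_THRESHOLD = 1e-6
_STEADY_TOL = 1e-9


@dataclass
class StoichModel:
    """Stoichiometric network with designated reactions.

    S is metabolites x reactions; bounds in mmol/(gDW h).  Designated ids
    locate the biomass reaction, the sucrose uptake exchange and (once
    present) the levansucrase synthesis pseudo-reaction.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    biomass_id: str
    sucrose_uptake_id: str
    levansucrase_id: str | None = None
    sucrose_metabolite_id: str | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        nm, nr = self.S.shape
        if nm != len(self.metabolite_ids) or nr != len(self.reaction_ids):
            raise ValueError("S dimensions inconsistent with id lists")
        if len(self.lb) != nr or len(self.ub) != nr:
            raise ValueError("bounds length mismatch")
        if np.any(self.lb > self.ub):
            raise ValueError("lower bound exceeds upper bound")
        for rid in (self.biomass_id, self.sucrose_uptake_id):
            if rid not in self.reaction_ids:
                raise ValueError(
                    f"designated reaction {rid!r} missing; candidates: "
                    f"{self.reaction_ids}"
                )

    # -- bookkeeping -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def rxn_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(
                f"reaction {rid!r} not in model; candidates: {self.reaction_ids}"
            ) from None

    def copy(self) -> "StoichModel":
        return StoichModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(), lb=self.lb.copy(), ub=self.ub.copy(),
            biomass_id=self.biomass_id,
            sucrose_uptake_id=self.sucrose_uptake_id,
            levansucrase_id=self.levansucrase_id,
            sucrose_metabolite_id=self.sucrose_metabolite_id,
        )

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        j = self.rxn_index(rid)
        self.lb[j], self.ub[j] = lb, ub

    # -- cobra conversion ---------------------------------------------
    def to_cobra(self):
        import cobra

        model = cobra.Model("stoich_model")
        mets = {mid: cobra.Metabolite(mid, compartment="c")
                for mid in self.metabolite_ids}
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            rxn = cobra.Reaction(rid)
            rxn.lower_bound, rxn.upper_bound = float(self.lb[j]), float(self.ub[j])
            rxns.append(rxn)
        model.add_reactions(rxns)
        for j, rid in enumerate(self.reaction_ids):
            coeffs = {mets[mid]: float(self.S[i, j])
                      for i, mid in enumerate(self.metabolite_ids)
                      if self.S[i, j] != 0}
            model.reactions.get_by_id(rid).add_metabolites(coeffs)
        model.objective = model.reactions.get_by_id(self.biomass_id)
        return model

    @classmethod
    def from_cobra(cls, model, biomass_id: str, sucrose_uptake_id: str,
                   levansucrase_id: str | None = None,
                   sucrose_metabolite_id: str | None = None) -> "StoichModel":
        met_ids = sorted(m.id for m in model.metabolites)
        rxn_ids = [r.id for r in model.reactions]
        S = np.zeros((len(met_ids), len(rxn_ids)))
        lb = np.zeros(len(rxn_ids))
        ub = np.zeros(len(rxn_ids))
        for j, rxn in enumerate(model.reactions):
            lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
            for met, coeff in rxn.metabolites.items():
                S[met_ids.index(met.id), j] = coeff
        return cls(metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
                   lb=lb, ub=ub, biomass_id=biomass_id,
                   sucrose_uptake_id=sucrose_uptake_id,
                   levansucrase_id=levansucrase_id,
                   sucrose_metabolite_id=sucrose_metabolite_id)


def load_stoich_model(path, biomass_id: str, sucrose_uptake_id: str,
                      levansucrase_id: str | None = None,
                      sucrose_metabolite_id: str | None = None,
                      require_levansucrase: bool = False) -> StoichModel:
    """Read an SBML (L3+FBC) model and resolve the designated reactions."""
    from cobra.io import read_sbml_model

    model = read_sbml_model(str(path))
    rxn_ids = [r.id for r in model.reactions]
    for rid, what in ((biomass_id, "biomass"),
                      (sucrose_uptake_id, "sucrose uptake")):
        if rid not in rxn_ids:
            raise KeyError(f"{what} reaction {rid!r} not found; candidates "
                           f"include {rxn_ids[:20]}...")
    if levansucrase_id is not None and levansucrase_id not in rxn_ids:
        if require_levansucrase:
            raise KeyError(
                f"levansucrase reaction {levansucrase_id!r} not found and no "
                f"augmentation requested"
            )
        levansucrase_id = None
    return StoichModel.from_cobra(model, biomass_id, sucrose_uptake_id,
                                  levansucrase_id, sucrose_metabolite_id)


def save_stoich_model(m: StoichModel, path) -> None:
    """Write the network as SBML L3+FBC."""
    from cobra.io import write_sbml_model

    write_sbml_model(m.to_cobra(), str(path))


def augment_levansucrase(
    m: StoichModel,
    composition: dict[str, float] | None = None,
    reaction_id: str = "LEVS_SYN",
    secretion_id: str = "EX_levs",
    product_metabolite: str = "levs",
) -> StoichModel:
    """Add a levansucrase-protein synthesis pseudo-reaction and secretion.

    ``composition`` maps metabolite id to the amount drained per mmol of
    protein (positive numbers).  The default is a uniform placeholder
    (10 amino-acid units from 'aa' plus 20 ATP equivalents) and is NOT an
    experimentally determined composition.
    """
    if m.levansucrase_id is not None:
        raise ValueError("model already has a levansucrase reaction "
                         f"({m.levansucrase_id})")
    composition = composition or {"aa": 10.0, "atp": 20.0}
    unknown = [mid for mid in composition if mid not in m.metabolite_ids]
    if unknown:
        raise KeyError(f"composition references unknown metabolites: {unknown}")

    out = m.copy()
    out.metabolite_ids.append(product_metabolite)
    nm, nr = out.S.shape
    S = np.zeros((nm + 1, nr + 2))
    S[:nm, :nr] = out.S
    j_syn, j_exc = nr, nr + 1
    for mid, amount in composition.items():
        S[out.metabolite_ids.index(mid), j_syn] = -abs(amount)
    S[nm, j_syn] = 1.0
    S[nm, j_exc] = -1.0
    out.S = S
    out.reaction_ids += [reaction_id, secretion_id]
    out.lb = np.concatenate([out.lb, [0.0, 0.0]])
    out.ub = np.concatenate([out.ub, [1000.0, 1000.0]])
    out.levansucrase_id = reaction_id
    return out


def remove_levansucrase(m: StoichModel,
                        secretion_id: str = "EX_levs",
                        product_metabolite: str = "levs") -> StoichModel:
    """Inverse of :func:`augment_levansucrase` (id-level)."""
    if m.levansucrase_id is None:
        raise ValueError("model has no levansucrase reaction")
    keep_r = [j for j, rid in enumerate(m.reaction_ids)
              if rid not in (m.levansucrase_id, secretion_id)]
    keep_m = [i for i, mid in enumerate(m.metabolite_ids)
              if mid != product_metabolite]
    return StoichModel(
        metabolite_ids=[m.metabolite_ids[i] for i in keep_m],
        reaction_ids=[m.reaction_ids[j] for j in keep_r],
        S=m.S[np.ix_(keep_m, keep_r)],
        lb=m.lb[keep_r], ub=m.ub[keep_r],
        biomass_id=m.biomass_id, sucrose_uptake_id=m.sucrose_uptake_id,
        levansucrase_id=None, sucrose_metabolite_id=m.sucrose_metabolite_id,
    )


# --- coupling -------------------------------------------------------------

@dataclass(frozen=True)
class CouplingConstraints:
    """Snapshot constraints handed from the kinetic to the metabolic model.

    mu_monod (1/h) fixes the biomass flux; sucrose_uptake_flux
    (mmol/(gDW h), = mu/Y_XS on the kinetic side) fixes the uptake
    exchange; alpha (mg/gDW) fixes the levansucrase synthesis flux at
    ``alpha * mu / levansucrase_mw``.
    """

    mu_monod: float
    sucrose_uptake_flux: float
    alpha: float
    levansucrase_mw: float = LEVANSUCRASE_MW
    snapshot_time: float = 9.0

    def __post_init__(self):
        if self.mu_monod < 0 or self.sucrose_uptake_flux < 0 or self.alpha < 0:
            raise ValueError("coupling values must be non-negative")
        if self.levansucrase_mw <= 0:
            raise ValueError("levansucrase_mw must be positive")

    @property
    def levansucrase_flux(self) -> float:
        """mmol protein/(gDW h)."""
        return self.alpha * self.mu_monod / self.levansucrase_mw

    @classmethod
    def from_kinetics(cls, p, S_reactor_mM: float,
                      snapshot_time: float = 9.0,
                      levansucrase_mw: float = LEVANSUCRASE_MW
                      ) -> "CouplingConstraints":
        """Build constraints from a parameter set and the reactor sucrose
        concentration at the snapshot (mid-exponential phase, 9 h default)."""
        from .kinetic_core import growth_rate

        mu = float(growth_rate(p, S_reactor_mM))
        return cls(mu_monod=mu, sucrose_uptake_flux=mu / p.Y_XS,
                   alpha=p.alpha, levansucrase_mw=levansucrase_mw,
                   snapshot_time=snapshot_time)


def apply_coupling(m: StoichModel, c: CouplingConstraints,
                   relaxed: bool = False) -> StoichModel:
    """Fix the designated fluxes to the kinetic snapshot values.

    Default encodes the printed equalities as lb=ub; ``relaxed=True`` uses
    upper bounds only (feasibility diagnosis).  Raises after a feasibility
    probe naming the binding constraint if the coupled model is infeasible.
    """
    if m.levansucrase_id is None:
        raise ValueError("model lacks a levansucrase reaction; augment first")
    out = m.copy()
    fixed = {
        m.biomass_id: c.mu_monod,
        m.sucrose_uptake_id: c.sucrose_uptake_flux,
        m.levansucrase_id: c.levansucrase_flux,
    }
    for rid, value in fixed.items():
        if relaxed:
            out.set_bounds(rid, 0.0, value)
        else:
            out.set_bounds(rid, value, value)
    if not _is_feasible(out):
        # probe: relax each coupled equality in turn
        for rid in fixed:
            probe = out.copy()
            probe.set_bounds(rid, 0.0, np.inf)
            if _is_feasible(probe):
                raise ValueError(
                    f"coupled model infeasible; binding constraint: {rid} = "
                    f"{fixed[rid]:.6g}"
                )
        raise ValueError("coupled model infeasible (jointly binding constraints)")
    return out


def _is_feasible(m: StoichModel) -> bool:
    res = linprog(c=np.zeros(m.n_reactions), A_eq=m.S, b_eq=np.zeros(m.n_metabolites),
                  bounds=list(zip(m.lb, m.ub)), method="highs")
    return res.status == 0


# --- LP solving -----------------------------------------------------------

@dataclass
class FluxSolution:
    """Flux vector with the minimal-total-flux objective value."""

    reaction_ids: list[str]
    fluxes: np.ndarray                 # net fluxes, mmol/(gDW h)
    total_abs_flux: float
    status: str
    objective_reaction: str | None = None
    objective_value: float | None = None

    def flux(self, rid: str) -> float:
        return float(self.fluxes[self.reaction_ids.index(rid)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.fluxes, index=self.reaction_ids, name="flux")


def _split_irreversible(m: StoichModel):
    """Columns for the irreversible reformulation: a forward column for
    every reaction plus a backward column for each reversible one."""
    cols, col_bounds, owners, signs = [], [], [], []
    for j in range(m.n_reactions):
        lo, hi = m.lb[j], m.ub[j]
        f_lo, f_hi = max(lo, 0.0), max(hi, 0.0)
        cols.append(m.S[:, j])
        col_bounds.append((f_lo, f_hi))
        owners.append(j)
        signs.append(+1.0)
        if lo < 0:
            b_lo, b_hi = max(-hi, 0.0), -lo
            cols.append(-m.S[:, j])
            col_bounds.append((b_lo, b_hi))
            owners.append(j)
            signs.append(-1.0)
    A = np.column_stack(cols)
    return A, col_bounds, np.array(owners), np.array(signs)


def solve_min_total_flux(m: StoichModel) -> FluxSolution:
    """Minimise total absolute flux subject to steady state and bounds.

    Reversible reactions are split into irreversible forward/backward
    pairs; the LP minimises the sum over split variables; net fluxes are
    recombined.  Raises on infeasible or unbounded problems.
    """
    A, col_bounds, owners, signs = _split_irreversible(m)
    res = linprog(c=np.ones(A.shape[1]), A_eq=A, b_eq=np.zeros(m.n_metabolites),
                  bounds=col_bounds, method="highs")
    if res.status == 2:
        raise ValueError("minimal-total-flux problem is infeasible")
    if res.status == 3:
        raise ValueError("minimal-total-flux problem is unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    net = np.zeros(m.n_reactions)
    for v, j, s in zip(res.x, owners, signs):
        net[j] += s * v
    resid = np.abs(m.S @ net).max()
    if resid > _STEADY_TOL:
        raise RuntimeError(f"steady-state residual {resid:.3e} above tolerance")
    return FluxSolution(reaction_ids=list(m.reaction_ids), fluxes=net,
                        total_abs_flux=float(res.fun), status="optimal")


def solve_fba(m: StoichModel, objective_id: str,
              sense: str = "max") -> FluxSolution:
    """Plain FBA: optimise one reaction's flux subject to steady state."""
    j = m.rxn_index(objective_id)
    c = np.zeros(m.n_reactions)
    c[j] = -1.0 if sense == "max" else 1.0
    res = linprog(c=c, A_eq=m.S, b_eq=np.zeros(m.n_metabolites),
                  bounds=list(zip(m.lb, m.ub)), method="highs")
    if res.status == 2:
        raise ValueError(f"FBA infeasible for objective {objective_id}")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return FluxSolution(reaction_ids=list(m.reaction_ids), fluxes=res.x,
                        total_abs_flux=float(np.sum(np.abs(res.x))),
                        status="optimal", objective_reaction=objective_id,
                        objective_value=float(res.x[j]))


# --- analysis -------------------------------------------------------------

def flux_sum(sol: FluxSolution, m: StoichModel,
             normalize: bool = True) -> pd.DataFrame:
    """Per-metabolite turnover Phi_i = 1/2 * sum_j |S_ij v_j|.

    With ``normalize=True`` a second column divides by the sucrose uptake
    flux (raises if the uptake is zero).
    """
    phi = 0.5 * np.abs(m.S * sol.fluxes[None, :]).sum(axis=1)
    out = pd.DataFrame({"metabolite": m.metabolite_ids, "flux_sum": phi})
    if normalize:
        uptake = abs(sol.flux(m.sucrose_uptake_id))
        if uptake == 0:
            raise ValueError("sucrose uptake flux is zero; cannot normalise")
        out["flux_sum_normalized"] = phi / uptake
    return out.set_index("metabolite")


_CATEGORIES = {
    (True, True, True): "active_all",
    (True, False, False): "active_low_only",
    (False, True, True): "active_transition_high",
    (False, False, False): "inactive_all",
}


def classify_activity(solutions: dict[str, FluxSolution],
                      threshold: float = ACTIVITY_THRESHOLD) -> pd.DataFrame:
    """Activity category per reaction across the three sucrose conditions.

    ``solutions`` maps 'low', 'transition', 'high' to flux solutions over
    the same reaction set.  A reaction is active in a condition when
    |flux| >= threshold.  The four named patterns are labelled; anything
    else is 'other'.
    """
    required = ("low", "transition", "high")
    missing = [k for k in required if k not in solutions]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    ids = solutions["low"].reaction_ids
    for k in required:
        if solutions[k].reaction_ids != ids:
            raise ValueError("reaction sets differ between conditions")
    rows = []
    for i, rid in enumerate(ids):
        act = tuple(abs(solutions[k].fluxes[i]) >= threshold for k in required)
        rows.append({
            "reaction": rid,
            **{f"active_{k}": a for k, a in zip(required, act)},
            "category": _CATEGORIES.get(act, "other"),
        })
    return pd.DataFrame(rows).set_index("reaction")
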