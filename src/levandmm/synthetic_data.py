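"""Synthetic fermentation time courses and the toy metabolic network.

``generate_timecourses`` emulates the measurement campaign the kinetic
model is calibrated against: batch cultures at initial sucrose 50, 100,
200, 250 and 300 g/L, sampled at 6, 12, 18, 24, 30, 36, 48, 60, 72, 96
and 120 h, with multiplicative lognormal measurement noise (default CV
3%, the scale suggested by the replicate SDs of the production summary
table) and a detection floor.

``generate_toy_gem`` builds the small mass-balanced stoichiometric
network used as a stand-in for the genome-scale model in all tests; it
deliberately contains the glucose-6-phosphate branch point (PGI-analog
vs G6PDH-analog), an amino-acid precursor exchange, and a levansucrase
synthesis pseudo-reaction so every coupling and scenario operation can
be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ObservedTimecourse
from .kinetic_core import KineticParameterSet
from .simulator import SAMPLING_GRID, SimulationConfig, simulate_batch, select_regime

__all__ = ["NoiseModel", "generate_timecourses", "generate_toy_gem",
           "DEFAULT_CONDITIONS", "TOY_DESIGNATIONS"]

#: initial sucrose concentrations of the study, g/L
DEFAULT_CONDITIONS = (50.0, 100.0, 200.0, 250.0, 300.0)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    cv: coefficient of variation per species (scalar applied to all);
    floor: detection floor in measurement units (g/L, gDW/L);
    kind: 'lognormal' (default) or 'additive' Gaussian with sd = cv *
    species-wise mean signal.
    """

    cv: float = 0.03
    floor: float = 0.0
    kind: str = "lognormal"

    def __post_init__(self):
        if self.cv < 0 or self.floor < 0:
            raise ValueError("cv and floor must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            noisy = np.asarray(values, dtype=float).copy()
        elif self.kind == "lognormal":
            sigma = np.sqrt(np.log1p(self.cv**2))
            # mean-one lognormal factor
            factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                    size=np.shape(values))
            noisy = values * factors
        elif self.kind == "additive":
            sd = self.cv * np.mean(np.abs(values))
            noisy = values + rng.normal(0.0, sd, size=np.shape(values))
        else:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        return np.where(noisy < self.floor, self.floor, noisy)


def generate_timecourses(
    params: dict[float, KineticParameterSet] | None = None,
    conditions=DEFAULT_CONDITIONS,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 1,
    seed: int = 0,
    times=SAMPLING_GRID,
    X0: float = 0.05,
) -> list[ObservedTimecourse]:
    """Simulate each condition with its regime parameters and add noise.

    ``params`` maps initial sucrose (g/L) to a parameter set; conditions
    absent from the map fall back to ``select_regime``.  Deterministic
    under a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for cond in conditions:
        p = (params or {}).get(cond) or select_regime(cond)
        grid = tuple(sorted(set([0.0] + list(times))))
        cfg = SimulationConfig(initial_sucrose=cond, X0=X0,
                               horizon=max(grid), report_grid=grid)
        traj = simulate_batch(cfg, p)
        wide = traj.to_frame(measurement_units=True)
        wide = wide[wide["time"].isin(times)]
        clean = {sp: wide[sp].to_numpy() for sp in
                 ("biomass", "sucrose", "glucose", "fructose", "levan")}
        for rep in range(replicates):
            measurements = {sp: noise.apply(v, rng) for sp, v in clean.items()}
            out.append(ObservedTimecourse(
                condition=cond,
                times=np.asarray(sorted(times), dtype=float),
                measurements=measurements,
                replicate=rep,
            ))
    return out


# --- toy stoichiometric network ------------------------------------------

#: designated reaction ids of the toy network (config map the coupling uses)
TOY_DESIGNATIONS = {
    "biomass": "BIOMASS",
    "sucrose_uptake": "EX_suc",
    "levansucrase": "LEVS_SYN",
    "levansucrase_secretion": "EX_levs",
    "pgi": "PGI",
    "g6pdh": "G6PDH",
    "precursor_exchange": "EX_aa",
}

# reaction id -> ({metabolite: coeff}, lb, ub); negative coeff = consumed
_TOY_REACTIONS = {
    # exchanges (one-sided columns)
    "EX_suc":   ({"suc": 1.0}, 0.0, 1000.0),           # sucrose uptake
    "EX_o2":    ({"o2": 1.0}, 0.0, 1000.0),            # oxygen uptake
    "EX_aa":    ({"aa": 1.0}, 0.0, 0.0),               # amino-acid supplement, closed
    "EX_pyr":   ({"pyr": -1.0}, 0.0, 1000.0),          # overflow secretion
    "EX_levs":  ({"levs": -1.0}, 0.0, 1000.0),         # levansucrase secretion
    "EX_bio":   ({"biomass": -1.0}, 0.0, 1000.0),      # biomass drain
    # metabolism
    "INV":      ({"suc": -1.0, "g6p": 2.0, "atp": -1.0}, 0.0, 1000.0),
    "PGI":      ({"g6p": -1.0, "f6p": 1.0}, -1000.0, 1000.0),  # reversible
    "G6PDH":    ({"g6p": -1.0, "pent": 1.0, "nadph": 2.0}, 0.0, 1000.0),
    "TKT":      ({"pent": -1.0, "f6p": 1.0}, 0.0, 1000.0),     # non-oxidative PPP lump
    "GLYC":     ({"f6p": -1.0, "pyr": 2.0, "atp": 2.0}, 0.0, 1000.0),
    "TCA":      ({"pyr": -1.0, "o2": -1.0, "atp": 4.0}, 0.0, 1000.0),
    "AA_SYN":   ({"pyr": -1.0, "atp": -2.0, "nadph": -1.0, "aa": 1.0}, 0.0, 1000.0),
    "BIOMASS":  ({"g6p": -0.5, "aa": -0.3, "atp": -10.0, "biomass": 1.0}, 0.0, 1000.0),
    "LEVS_SYN": ({"aa": -10.0, "atp": -20.0, "levs": 1.0}, 0.0, 1000.0),
    "ATPM":     ({"atp": -1.0}, 0.0, 1000.0),          # maintenance / energy sink
    "NADPHOX":  ({"nadph": -1.0}, 0.0, 1000.0),        # reducing-equivalent sink
}


def generate_toy_gem(include_levansucrase: bool = True):
    """Build the packaged toy stoichiometric network as a ``StoichModel``.

    With ``include_levansucrase=False`` the levansucrase synthesis
    pseudo-reaction and its secretion exchange are omitted, which is the
    starting point the augmentation operation expects.
    """
    from .gem_coupling import StoichModel

    reactions = dict(_TOY_REACTIONS)
    if not include_levansucrase:
        reactions.pop("LEVS_SYN")
        reactions.pop("EX_levs")
    met_ids = sorted({m for stoich, _, _ in reactions.values() for m in stoich})
    rxn_ids = list(reactions)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        stoich, lo, hi = reactions[rid]
        lb[j], ub[j] = lo, hi
        for met, coeff in stoich.items():
            S[met_ids.index(met), j] = coeff
    return StoichModel(
        metabolite_ids=met_ids,
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        biomass_id="BIOMASS",
        sucrose_uptake_id="EX_suc",
        levansucrase_id="LEVS_SYN" if include_levansucrase else None,
        #: the uptake column feeds this metabolite; flux-sum normalisation anchor
        sucrose_metabolite_id="suc",
    )
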