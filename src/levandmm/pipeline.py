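"""End-to-end orchestration: data generation, calibration, simulation,
metric summaries, snapshot coupling, flux analysis and scenarios.

Every stage writes its table under the output directory and contributes
to a machine-readable JSON report.  All randomness flows from the single
master seed; reruns with the same seed give identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .calibration import fit_parameters, nrmse_table, sensitivity_scan
from .gem_coupling import (
    CouplingConstraints,
    apply_coupling,
    classify_activity,
    flux_sum,
    solve_min_total_flux,
)
from .metrics import summarize_production
from .presets import PRESETS
from .scenarios import (
    ALPHA_SWEEP,
    run_alpha_perturbation,
    run_knockdown,
    run_supplementation,
)
from .simulator import SimulationConfig, select_regime, simulate_batch
from .synthetic_data import (
    DEFAULT_CONDITIONS,
    NoiseModel,
    TOY_DESIGNATIONS,
    generate_timecourses,
    generate_toy_gem,
)

__all__ = ["run_full_analysis"]

_REGIME_CONDITION = {"low": 100.0, "transition": 200.0, "high": 250.0}


def run_full_analysis(
    outdir,
    seed: int = 0,
    conditions=DEFAULT_CONDITIONS,
    noise_cv: float = 0.03,
    replicates: int = 3,
    fit_free_params=("mu_max", "alpha"),
    fit_n_starts: int = 3,
    snapshot_time: float = 9.0,
    stoich_model=None,
    run_sensitivity: bool = False,
) -> dict:
    """Run every pipeline stage on synthetic data and the toy network.

    Returns the report dict (also written to ``report.json``).  Stage
    outputs land as CSV/TSV next to it.  A custom ``stoich_model``
    (e.g. a published genome-scale model already carrying the designated
    reactions) replaces the packaged toy network when supplied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    report: dict = {"seed": seed, "stages": {}}

    # 1. synthetic observations
    datasets = generate_timecourses(
        conditions=conditions, noise=NoiseModel(cv=noise_cv),
        replicates=replicates, seed=int(rng.integers(2**31)),
    )
    pd.concat([d.to_frame() for d in datasets]).to_csv(
        outdir / "timecourses.csv", index=False)
    report["stages"]["generate"] = {
        "conditions": list(conditions), "replicates": replicates,
        "noise_cv": noise_cv, "n_timecourses": len(datasets),
    }

    # 2. per-regime calibration
    fits = {}
    for regime, cond in _REGIME_CONDITION.items():
        obs = [d for d in datasets if d.condition == cond]
        if not obs:
            continue
        fit = fit_parameters(obs, PRESETS[regime],
                             free_params=fit_free_params,
                             seed=int(rng.integers(2**31)),
                             n_starts=fit_n_starts)
        fits[regime] = fit
    with open(outdir / "fits.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh, indent=2)
    report["stages"]["fit"] = {
        regime: {"nrmse_average": fit.nrmse_average,
                 "sse": fit.sse,
                 "fitted": {n: getattr(fit.fitted, n)
                            for n in fit.free_params}}
        for regime, fit in fits.items()
    }

    # 3. simulation + production metrics per condition
    summaries = []
    trajectories = {}
    for cond in conditions:
        p = select_regime(cond)
        traj = simulate_batch(SimulationConfig(initial_sucrose=cond), p)
        trajectories[cond] = traj
        traj.to_frame(measurement_units=True).to_csv(
            outdir / f"trajectory_{int(cond)}.csv", index=False)
        summaries.append(summarize_production(traj, cond).to_row())
    metrics_table = pd.concat(summaries, ignore_index=True)
    metrics_table.to_csv(outdir / "production_metrics.csv", index=False)
    report["stages"]["metrics"] = metrics_table.to_dict(orient="records")

    # 4. snapshot coupling + flux analysis on the stoichiometric model
    model = stoich_model if stoich_model is not None else generate_toy_gem()
    solutions = {}
    flux_sums = {}
    couplings = {}
    for regime, cond in _REGIME_CONDITION.items():
        p = PRESETS[regime]
        traj = simulate_batch(
            SimulationConfig(initial_sucrose=cond,
                             report_grid=(0.0, snapshot_time)), p)
        S_snap = float(traj.series("S_reactor")[-1])
        c = CouplingConstraints.from_kinetics(p, S_snap,
                                              snapshot_time=snapshot_time)
        couplings[regime] = c
        coupled = apply_coupling(model, c)
        sol = solve_min_total_flux(coupled)
        solutions[regime] = sol
        flux_sums[regime] = flux_sum(sol, model)
    flux_table = pd.DataFrame({r: s.to_series() for r, s in solutions.items()})
    flux_table.to_csv(outdir / "fluxes.tsv", sep="\t")
    fs_table = pd.concat(
        {r: t["flux_sum_normalized"] for r, t in flux_sums.items()}, axis=1)
    fs_table.to_csv(outdir / "flux_sums.tsv", sep="\t")
    activity = classify_activity(solutions)
    activity.to_csv(outdir / "activity_classes.tsv", sep="\t")
    report["stages"]["couple"] = {
        regime: {"mu": c.mu_monod, "uptake": c.sucrose_uptake_flux,
                 "levansucrase_flux": c.levansucrase_flux,
                 "total_abs_flux": solutions[regime].total_abs_flux}
        for regime, c in couplings.items()
    }
    report["stages"]["activity"] = (
        activity["category"].value_counts().to_dict())

    # 5. scenarios (at the transitional condition)
    cfg200 = SimulationConfig(initial_sucrose=200.0)
    alpha_res = run_alpha_perturbation(cfg200, PRESETS["transition"],
                                       ALPHA_SWEEP)
    alpha_res.summary.to_csv(outdir / "scenario_alpha.csv", index=False)

    c_tr = couplings["transition"]
    coupled_tr = apply_coupling(model, c_tr)
    supp_res = run_supplementation(
        model, c_tr, exchange_id=TOY_DESIGNATIONS["precursor_exchange"],
        supply_bound=1.0)
    supp_res.summary.to_csv(outdir / "scenario_supplementation.csv",
                            index=False)
    kd_res = run_knockdown(
        coupled_tr, c_tr, reaction_id=TOY_DESIGNATIONS["pgi"],
        new_upper_bound=0.006,
        branch_points={"PGI": TOY_DESIGNATIONS["pgi"],
                       "G6PDH": TOY_DESIGNATIONS["g6pdh"]})
    kd_res.summary.to_csv(outdir / "scenario_knockdown.tsv", sep="\t")
    report["stages"]["scenarios"] = {
        "alpha": alpha_res.summary.to_dict(orient="records"),
        "supplementation": supp_res.summary.to_dict(orient="records")[0],
        "knockdown": {
            "pgi_flux": kd_res.summary.loc[TOY_DESIGNATIONS["pgi"],
                                           "flux_knockdown"],
            "g6pdh_direction": kd_res.summary.loc[TOY_DESIGNATIONS["g6pdh"],
                                                  "direction"],
        },
    }

    # 6. optional sensitivity scan
    if run_sensitivity:
        scan = sensitivity_scan(PRESETS["high"],
                                SimulationConfig(initial_sucrose=250.0))
        scan.to_csv(outdir / "sensitivity.csv", index=False)
        report["stages"]["sensitivity"] = (
            scan.groupby("parameter")["nrmse_vs_baseline"].mean()
            .sort_values(ascending=False).to_dict())

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
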