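import numpy as np
import pytest

from levandmm.gem_coupling import (
    CouplingConstraints,
    FluxSolution,
    StoichModel,
    apply_coupling,
    augment_levansucrase,
    classify_activity,
    flux_sum,
    load_stoich_model,
    remove_levansucrase,
    save_stoich_model,
    solve_fba,
    solve_min_total_flux,
)
from levandmm.presets import PRESETS
from levandmm.simulator import SimulationConfig, simulate_batch
from levandmm.synthetic_data import generate_toy_gem


def make_model(reactions, biomass_id, uptake_id, **kwargs):
    """Small helper: reactions = {id: ({met: coeff}, lb, ub)}."""
    met_ids = sorted({m for st, _, _ in reactions.values() for m in st})
    rxn_ids = list(reactions)
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb, ub = np.zeros(len(rxn_ids)), np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        st, lo, hi = reactions[rid]
        lb[j], ub[j] = lo, hi
        for met, coeff in st.items():
            S[met_ids.index(met), j] = coeff
    return StoichModel(metabolite_ids=met_ids, reaction_ids=rxn_ids, S=S,
                       lb=lb, ub=ub, biomass_id=biomass_id,
                       sucrose_uptake_id=uptake_id, **kwargs)


@pytest.fixture
def chain_model():
    """uptake -> A -> B -> C -> drain, uptake fixed at 1."""
    return make_model({
        "UP": ({"A": 1.0}, 1.0, 1.0),
        "R1": ({"A": -1.0, "B": 1.0}, 0.0, 10.0),
        "R2": ({"B": -1.0, "C": 1.0}, 0.0, 10.0),
        "OUT": ({"C": -1.0}, 0.0, 10.0),
    }, biomass_id="OUT", uptake_id="UP")


@pytest.fixture
def coupled_toy(toy_gem, transition_params):
    traj = simulate_batch(SimulationConfig(initial_sucrose=200.0,
                                           report_grid=(0.0, 9.0)),
                          transition_params)
    c = CouplingConstraints.from_kinetics(transition_params,
                                          float(traj.series("S_reactor")[-1]))
    return apply_coupling(toy_gem, c), c


class TestModelIO:
    def test_sbml_round_trip_preserves_network(self, toy_gem, tmp_path):
        path = tmp_path / "toy.xml"
        save_stoich_model(toy_gem, path)
        back = load_stoich_model(path, biomass_id="BIOMASS",
                                 sucrose_uptake_id="EX_suc",
                                 levansucrase_id="LEVS_SYN",
                                 sucrose_metabolite_id="suc")
        assert back.reaction_ids == toy_gem.reaction_ids
        assert back.metabolite_ids == toy_gem.metabolite_ids
        np.testing.assert_allclose(back.S, toy_gem.S)
        np.testing.assert_allclose(back.lb, toy_gem.lb)
        np.testing.assert_allclose(back.ub, toy_gem.ub)

    def test_missing_designated_reaction_reported(self, toy_gem, tmp_path):
        path = tmp_path / "toy.xml"
        save_stoich_model(toy_gem, path)
        with pytest.raises(KeyError, match="biomass"):
            load_stoich_model(path, biomass_id="NOPE",
                              sucrose_uptake_id="EX_suc")
        with pytest.raises(KeyError, match="levansucrase"):
            load_stoich_model(path, biomass_id="BIOMASS",
                              sucrose_uptake_id="EX_suc",
                              levansucrase_id="MISSING",
                              require_levansucrase=True)

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError):
            StoichModel(metabolite_ids=["A"], reaction_ids=["R1", "R2"],
                        S=np.zeros((1, 1)), lb=[0.0], ub=[1.0],
                        biomass_id="R1", sucrose_uptake_id="R2")


class TestAugmentation:
    def test_augment_then_remove_restores_model(self, toy_gem_bare):
        aug = augment_levansucrase(toy_gem_bare)
        back = remove_levansucrase(aug)
        assert back.reaction_ids == toy_gem_bare.reaction_ids
        assert back.metabolite_ids == toy_gem_bare.metabolite_ids
        np.testing.assert_allclose(back.S, toy_gem_bare.S)

    def test_augmented_model_supports_levansucrase_flux(self, toy_gem_bare):
        aug = augment_levansucrase(toy_gem_bare)
        m = aug.copy()
        m.set_bounds("EX_suc", 0.0, 10.0)
        sol = solve_fba(m, "LEVS_SYN")
        assert sol.objective_value > 0.0

    def test_composition_drain_stoichiometry(self, toy_gem_bare):
        comp = {"aa": 7.0, "atp": 13.0}
        aug = augment_levansucrase(toy_gem_bare, composition=comp)
        j = aug.rxn_index("LEVS_SYN")
        # 1 mmol protein flux drains exactly the configured amounts
        flux = np.zeros(aug.n_reactions)
        flux[j] = 1.0
        drain = aug.S @ flux
        assert drain[aug.metabolite_ids.index("aa")] == pytest.approx(-7.0)
        assert drain[aug.metabolite_ids.index("atp")] == pytest.approx(-13.0)
        assert drain[aug.metabolite_ids.index("levs")] == pytest.approx(1.0)

    def test_unknown_composition_metabolite_rejected(self, toy_gem_bare):
        with pytest.raises(KeyError, match="unknown"):
            augment_levansucrase(toy_gem_bare, composition={"nonexistent": 1.0})

    def test_double_augmentation_rejected(self, toy_gem):
        with pytest.raises(ValueError):
            augment_levansucrase(toy_gem)


class TestApplyCoupling:
    def test_uptake_constraint_is_mu_over_yield(self, toy_gem):
        # mu=0.2454, Y=0.015 -> uptake 16.36 mmol/(gDW h)
        c = CouplingConstraints(mu_monod=0.2454, sucrose_uptake_flux=0.2454 / 0.015,
                                alpha=45.0)
        assert c.sucrose_uptake_flux == pytest.approx(16.36, abs=0.01)
        coupled = apply_coupling(toy_gem, c)
        j = coupled.rxn_index("EX_suc")
        assert coupled.lb[j] == coupled.ub[j] == pytest.approx(16.36, abs=0.01)

    def test_zero_growth_pins_biomass_and_enzyme_fluxes(self, toy_gem):
        c = CouplingConstraints(mu_monod=0.0, sucrose_uptake_flux=0.0, alpha=45.0)
        coupled = apply_coupling(toy_gem, c)
        sol = solve_min_total_flux(coupled)
        assert sol.flux("BIOMASS") == 0.0
        assert sol.flux("LEVS_SYN") == 0.0

    def test_fba_returns_biomass_flux_equal_to_growth_rate(self, coupled_toy):
        coupled, c = coupled_toy
        sol = solve_min_total_flux(coupled)
        assert sol.flux("BIOMASS") == pytest.approx(c.mu_monod, rel=1e-9)
        assert sol.flux("LEVS_SYN") == pytest.approx(c.levansucrase_flux,
                                                     rel=1e-9)

    def test_from_kinetics_snapshot_values(self, transition_params):
        c = CouplingConstraints.from_kinetics(transition_params, 500.0)
        p = transition_params
        mu = p.mu_max * 500.0 / (p.Ks + 500.0)
        assert c.mu_monod == pytest.approx(mu)
        assert c.sucrose_uptake_flux == pytest.approx(mu / p.Y_XS)
        assert c.levansucrase_flux == pytest.approx(
            p.alpha * mu / c.levansucrase_mw)

    def test_infeasible_coupling_names_binding_constraint(self, toy_gem):
        # uptake 0 cannot support positive growth
        c = CouplingConstraints(mu_monod=0.5, sucrose_uptake_flux=0.0,
                                alpha=45.0)
        with pytest.raises(ValueError, match="infeasible"):
            apply_coupling(toy_gem, c)

    def test_unaugmented_model_rejected(self, toy_gem_bare):
        c = CouplingConstraints(mu_monod=0.1, sucrose_uptake_flux=1.0, alpha=45.0)
        with pytest.raises(ValueError, match="levansucrase"):
            apply_coupling(toy_gem_bare, c)


class TestMinTotalFlux:
    def test_linear_chain_carries_uniform_flux(self, chain_model):
        sol = solve_min_total_flux(chain_model)
        np.testing.assert_allclose(sol.fluxes, 1.0)
        assert sol.total_abs_flux == pytest.approx(4.0)

    def test_parallel_routes_prefer_the_short_one(self):
        # demand 1 of C; route1: A->C (1 step), route2: A->B->C (2 steps)
        m = make_model({
            "UP": ({"A": 1.0}, 1.0, 1.0),
            "SHORT": ({"A": -1.0, "C": 1.0}, 0.0, 10.0),
            "L1": ({"A": -1.0, "B": 1.0}, 0.0, 10.0),
            "L2": ({"B": -1.0, "C": 1.0}, 0.0, 10.0),
            "OUT": ({"C": -1.0}, 1.0, 1.0),
        }, biomass_id="OUT", uptake_id="UP")
        sol = solve_min_total_flux(m)
        assert sol.flux("SHORT") == pytest.approx(1.0)
        assert sol.flux("L1") == pytest.approx(0.0, abs=1e-9)
        assert sol.total_abs_flux == pytest.approx(3.0)

    def test_contradictory_equalities_are_infeasible(self):
        m = make_model({
            "UP": ({"A": 1.0}, 1.0, 1.0),
            "R1": ({"A": -1.0, "B": 1.0}, 0.0, 10.0),
            "OUT": ({"B": -1.0}, 2.0, 2.0),
        }, biomass_id="OUT", uptake_id="UP")
        with pytest.raises(ValueError, match="infeasible"):
            solve_min_total_flux(m)

    def test_reversible_reaction_net_flux_recombined(self):
        # B is reachable only through a reversible carrier running backwards
        m = make_model({
            "UP": ({"A": 1.0}, 1.0, 1.0),
            "REV": ({"B": -1.0, "A": 1.0}, -10.0, 10.0),
            "OUT": ({"B": -1.0}, 0.0, 10.0),
        }, biomass_id="OUT", uptake_id="UP")
        sol = solve_min_total_flux(m)
        assert sol.flux("REV") == pytest.approx(-1.0)
        assert np.abs(m.S @ sol.fluxes).max() < 1e-9

    def test_steady_state_on_coupled_toy_model(self, coupled_toy):
        coupled, _ = coupled_toy
        sol = solve_min_total_flux(coupled)
        assert np.abs(coupled.S @ sol.fluxes).max() < 1e-9

    def test_matches_cobra_parsimonious_fba(self, coupled_toy):
        """Independent cross-check: cobrapy's parsimonious FBA on the same
        coupled network returns the same minimal total flux."""
        from cobra.flux_analysis import pfba

        coupled, _ = coupled_toy
        ours = solve_min_total_flux(coupled)
        ref = pfba(coupled.to_cobra())
        assert ours.total_abs_flux == pytest.approx(ref.objective_value,
                                                    rel=1e-6)

    def test_biomass_ceiling_decreases_with_enzyme_burden(self, toy_gem):
        """With uptake fixed and biomass free, forcing more flux through
        levansucrase synthesis can only lower the achievable growth."""
        previous = np.inf
        for levs_flux in (0.0, 0.05, 0.2):
            m = toy_gem.copy()
            m.set_bounds("EX_suc", 10.0, 10.0)
            m.set_bounds("LEVS_SYN", levs_flux, levs_flux)
            sol = solve_fba(m, "BIOMASS")
            assert sol.objective_value <= previous + 1e-9
            previous = sol.objective_value


class TestFluxSum:
    def test_chain_intermediate_turnover(self, chain_model):
        sol = solve_min_total_flux(chain_model)
        fs = flux_sum(sol, chain_model, normalize=False)
        assert fs.loc["B", "flux_sum"] == pytest.approx(1.0)

    def test_normalized_uptake_metabolite_is_one(self, coupled_toy):
        coupled, _ = coupled_toy
        sol = solve_min_total_flux(coupled)
        fs = flux_sum(sol, coupled)
        assert fs.loc["suc", "flux_sum_normalized"] == pytest.approx(1.0)

    def test_matches_direct_summation(self, coupled_toy):
        coupled, _ = coupled_toy
        sol = solve_min_total_flux(coupled)
        fs = flux_sum(sol, coupled, normalize=False)
        for i, met in enumerate(coupled.metabolite_ids):
            direct = 0.5 * sum(abs(coupled.S[i, j] * sol.fluxes[j])
                               for j in range(coupled.n_reactions))
            assert fs.loc[met, "flux_sum"] == pytest.approx(direct)

    def test_zero_uptake_normalization_rejected(self, chain_model):
        m = chain_model.copy()
        m.set_bounds("UP", 0.0, 0.0)
        m.set_bounds("OUT", 0.0, 10.0)
        sol = solve_min_total_flux(m)
        with pytest.raises(ValueError, match="uptake"):
            flux_sum(sol, m)


class TestActivityClassification:
    @staticmethod
    def _sol(fluxes):
        return FluxSolution(reaction_ids=["R1"], fluxes=np.array([fluxes]),
                            total_abs_flux=abs(fluxes), status="optimal")

    @pytest.mark.parametrize("low,tr,high,expected", [
        (1e-7, 1e-7, 1e-7, "inactive_all"),
        (0.5, 0.5, 0.5, "active_all"),
        (0.5, 0.0, 0.0, "active_low_only"),
        (0.0, 0.3, 0.3, "active_transition_high"),
        (0.5, 0.0, 0.5, "other"),
    ])
    def test_threshold_categories(self, low, tr, high, expected):
        table = classify_activity({"low": self._sol(low),
                                   "transition": self._sol(tr),
                                   "high": self._sol(high)})
        assert table.loc["R1", "category"] == expected

    def test_mismatched_reaction_sets_rejected(self):
        a = FluxSolution(reaction_ids=["R1"], fluxes=np.array([1.0]),
                         total_abs_flux=1.0, status="optimal")
        b = FluxSolution(reaction_ids=["R2"], fluxes=np.array([1.0]),
                         total_abs_flux=1.0, status="optimal")
        with pytest.raises(ValueError, match="differ"):
            classify_activity({"low": a, "transition": b, "high": a})
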