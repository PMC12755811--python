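"""FBA engine: optimality, bounds handling, robustness, chemostat flux,
rescaling, ATP yields, and agreement with an independent LP implementation."""

import numpy as np
import pytest

from hyaflux import (
    ChemostatMeasurement,
    MetabolicModel,
    Metabolite,
    Reaction,
    atp_yield_per_glucose,
    build_stoichiometric_matrix,
    chemostat_flux,
    fba,
    fix_growth_fraction,
    rescale_to_uptake,
    robustness,
)
from hyaflux.fba import FEASIBILITY_TOL, solve_lp

from conftest import build_chain_model


def to_cobra(model):
    """Independent LP oracle: rebuild the model in cobra (GLPK backend)."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment)
            for m in model.metabolites}
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
    cm.objective = model.objective_reaction
    return cm


def random_small_model(rng):
    """A random <=15-reaction network with bounded fluxes (never unbounded)."""
    n_mets = rng.integers(3, 7)
    n_internal = rng.integers(2, 10)
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(n_mets)] + [
        Metabolite(f"m{i}_e", compartment="e") for i in range(n_mets)
    ]
    rxns = []
    for i in range(n_mets):
        rxns.append(Reaction(f"EX_m{i}", {f"m{i}_e": -1.0},
                             float(rng.integers(-10, 1)), 10.0, kind="exchange"))
        rxns.append(Reaction(f"T{i}", {f"m{i}_e": -1.0, f"m{i}_c": 1.0},
                             -10.0, 10.0, kind="transport"))
    for j in range(n_internal):
        k = rng.integers(2, min(4, n_mets) + 1)
        chosen = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=k)
        if (coefs > 0).all() or (coefs < 0).all():
            coefs[0] = -coefs[0]
        stoich = {f"m{i}_c": float(c) for i, c in zip(chosen, coefs)}
        lb = -10.0 if rng.random() < 0.5 else 0.0
        rxns.append(Reaction(f"R{j}", stoich, lb, 10.0))
    model = MetabolicModel(
        id="random", metabolites=mets, reactions=rxns,
        objective_reaction=f"R{rng.integers(0, n_internal)}",
    )
    model.validate()
    return model


class TestFba:
    def test_linear_chain_forces_unique_growth(self):
        model = build_chain_model(uptake=10.0, biomass_coeff=10.0)
        sol = fba(model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(1.0, abs=1e-9)
        assert sol["EX_A_e"] == pytest.approx(-10.0, abs=1e-9)

    def test_forced_demand_without_supply_is_reported_infeasible(self):
        mets = [Metabolite("atp_c", compartment="c")]
        rxns = [Reaction("ATPM", {"atp_c": -1.0}, 1.0, 10.0, kind="pseudo")]
        model = MetabolicModel(metabolites=mets, reactions=rxns,
                               objective_reaction="ATPM")
        sol = fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_missing_objective_raises(self):
        model = build_chain_model()
        with pytest.raises(KeyError):
            fba(model, "NOPE")

    def test_steady_state_and_bounds_of_returned_solutions(
        self, native_model, recombinant_model
    ):
        for model in (native_model, recombinant_model):
            sol = fba(model)
            assert sol.steady_state_residual(model) <= FEASIBILITY_TOL
            for rxn in model.reactions:
                v = sol[rxn.id]
                assert rxn.lower_bound - 1e-9 <= v <= rxn.upper_bound + 1e-9

    def test_agrees_with_independent_solver_on_synthetic_model(self, native_model):
        theirs = to_cobra(native_model).optimize()
        mine = fba(native_model)
        assert mine.objective_value == pytest.approx(
            theirs.objective_value, rel=1e-6
        )

    def test_agrees_with_independent_solver_on_random_models(self):
        rng = np.random.default_rng(20240917)
        n_compared = 0
        for _ in range(20):
            model = random_small_model(rng)
            mine = fba(model)
            theirs = to_cobra(model).optimize()
            if mine.status == "optimal" and theirs.status == "optimal":
                assert mine.objective_value == pytest.approx(
                    theirs.objective_value, rel=1e-6, abs=1e-6
                )
                n_compared += 1
            else:
                assert (mine.status == "optimal") == (theirs.status == "optimal")
        assert n_compared >= 10  # the generator must mostly yield solvable LPs

    def test_relaxing_a_bound_never_decreases_the_optimum(self, native_model):
        rng = np.random.default_rng(7)
        base = fba(native_model).objective_value
        for _ in range(15):
            relaxed = native_model.copy()
            rxn = relaxed.reactions[rng.integers(len(relaxed.reactions))]
            if rng.random() < 0.5:
                rxn.lower_bound -= float(rng.uniform(0, 50))
            else:
                rxn.upper_bound += float(rng.uniform(0, 50))
            assert fba(relaxed).objective_value >= base - 1e-6


class TestFixGrowthFraction:
    def test_fraction_one_keeps_growth_at_optimum(self, native_model):
        mu = fba(native_model).objective_value
        pinned = fix_growth_fraction(native_model, 1.0)
        sol = fba(pinned, "EX_ha_e")
        assert sol["BIOMASS"] == pytest.approx(mu, rel=1e-6)

    def test_relaxing_growth_never_reduces_product_optimum(self, native_model):
        at_100 = fba(fix_growth_fraction(native_model, 1.0), "EX_ha_e")
        at_95 = fba(fix_growth_fraction(native_model, 0.95), "EX_ha_e")
        assert at_95.objective_value >= at_100.objective_value - 1e-9

    def test_matches_bilevel_grid_oracle(self, native_model):
        """Max product over growth in [0.95 mu*, mu*] equals the best of a
        dense grid of growth-pinned optimizations."""
        mu = fba(native_model).objective_value
        lp = fba(fix_growth_fraction(native_model, 0.95), "EX_ha_e").objective_value
        grid_best = max(
            solve_lp(native_model, {"EX_ha_e": 1.0}, "maximize",
                     extra_bounds={"BIOMASS": (g, g)}).objective_value
            for g in np.linspace(0.95 * mu, mu, 41)
        )
        assert lp == pytest.approx(grid_best, abs=1e-6)

    def test_invalid_fraction_rejected(self, native_model):
        with pytest.raises(ValueError):
            fix_growth_fraction(native_model, 0.0)


class TestRobustness:
    def test_single_point_at_current_bound_equals_plain_fba(self, native_model):
        o2 = native_model.reaction("EX_o2_e")
        curve = robustness(native_model, "BIOMASS", "EX_o2_e", [o2.lower_bound])
        assert curve.grid[0][1] == pytest.approx(
            fba(native_model).objective_value, rel=1e-9
        )

    def test_grid_equals_independent_refits(self, native_model):
        grid = [0.0, -1.0, -3.0, -7.0, -15.0]
        curve = robustness(native_model, "EX_ha_e", "EX_o2_e", grid)
        for bound, value in curve.grid:
            expected = solve_lp(
                native_model, {"EX_ha_e": 1.0}, "maximize",
                extra_bounds={"EX_o2_e": (bound, 1000.0)},
            ).objective_value
            assert value == pytest.approx(expected, abs=1e-9)

    def test_ha_vs_oxygen_allowance_is_non_decreasing(self, native_model):
        """More oxygen availability never hurts the HA optimum (the qualitative
        oxygen response of the fermentative producer)."""
        grid = [0.0, -2.0, -5.0, -10.0, -20.0, -40.0]
        curve = robustness(native_model, "EX_ha_e", "EX_o2_e", grid)
        values = [v for _, v in sorted(curve.grid, reverse=True)]  # 0 -> -40
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]  # oxygen genuinely helps

    def test_infeasible_grid_points_recorded_as_missing(self, native_model):
        # forcing strong oxygen *secretion* is impossible for this network
        curve = robustness(native_model, "EX_ha_e", "EX_o2_e", [500.0], fixed=True)
        assert curve.grid[0][1] is None


class TestChemostatFlux:
    @pytest.mark.parametrize(
        "d,cs,cf,x,expected",
        [
            (0.3, 10.0, 0.0, 2.0, 1.5),
            (0.5, 7.0, 7.0, 3.0, 0.0),
            (0.4, 0.0, 20.0, 1.0, -8.0),  # uptake is negative
        ],
    )
    def test_direct_substitution(self, d, cs, cf, x, expected):
        m = ChemostatMeasurement(d, cs, cf, x)
        assert chemostat_flux(m) == pytest.approx(expected)

    def test_nonpositive_biomass_rejected(self):
        with pytest.raises(ValueError):
            ChemostatMeasurement(0.3, 1.0, 0.0, 0.0)


class TestRescaleToUptake:
    @pytest.mark.parametrize("uptake", [18.56, 4.67])
    def test_scaling_factor(self, uptake):
        model = build_chain_model(uptake=uptake, biomass_coeff=1.0)
        sol = fba(model)
        scaled = rescale_to_uptake(sol, "EX_A_e", 100.0)
        assert scaled["EX_A_e"] == pytest.approx(-100.0)
        assert scaled["GROWTH"] == pytest.approx(sol["GROWTH"] * 100.0 / uptake)

    def test_steady_state_preserved(self, native_model):
        sol = fba(native_model)
        scaled = rescale_to_uptake(sol, "EX_glc__D_e", 100.0)
        assert scaled.steady_state_residual(native_model) <= FEASIBILITY_TOL * 10

    def test_zero_uptake_rejected(self, native_model):
        sol = fba(native_model)
        with pytest.raises(ValueError):
            rescale_to_uptake(sol, "EX_ha_e")  # zero at max growth


class TestAtpYield:
    def test_homolactic_network_yields_two_atp_per_glucose(self, native_model):
        """Anaerobic EMP + lactate: textbook 2 ATP per glucose."""
        assert atp_yield_per_glucose(native_model) == pytest.approx(2.0, abs=1e-6)

    def test_respiring_host_outperforms_fermenter(
        self, native_model, recombinant_model
    ):
        assert atp_yield_per_glucose(recombinant_model) > atp_yield_per_glucose(
            native_model
        )

    def test_yield_is_uptake_invariant(self, recombinant_model):
        y1 = atp_yield_per_glucose(recombinant_model, glucose_uptake=1.0)
        y2 = atp_yield_per_glucose(recombinant_model, glucose_uptake=2.0)
        assert y1 == pytest.approx(y2, rel=1e-9)

    def test_missing_maintenance_reaction_raises(self):
        with pytest.raises(KeyError):
            atp_yield_per_glucose(build_chain_model(), maintenance_reaction="ATPM")
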