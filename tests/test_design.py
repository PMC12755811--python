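"""Strain-design searches: iterative knockouts and alternate-optima targets."""

import itertools

import numpy as np
import pytest

from hyaflux import (
    AltOptimaConfig,
    SearchConfig,
    fba,
    fix_growth_fraction,
    iterative_knockout_search,
    knockout,
    moma,
    reference_state,
    regulation_targets,
    sample_alternate_optima,
)
from hyaflux.design import RegulationTarget
from hyaflux.fba import FluxDistribution

from conftest import build_branch_model, build_chain_model


class TestIterativeKnockoutSearch:
    def test_no_improving_deletion_yields_empty_list(self):
        """In a linear chain every knockout only kills growth, never raises
        the product (there is no product branch at all)."""
        model = build_chain_model()
        model.genes = ["gT"]
        model.reaction("At").gpr = __import__("hyaflux").parse_gpr("gT")
        cfg = SearchConfig(product_reaction="EX_A_e", max_depth=1)
        assert iterative_knockout_search(model, cfg) == []

    def test_matches_exhaustive_enumeration_on_toy(self):
        """Depth-2 search output equals brute-force enumeration of all 1- and
        2-gene knockouts evaluated with fresh MOMA calls and the same
        keep/prune rules."""
        model = build_branch_model()
        cfg = SearchConfig(product_reaction="EX_Q_e", max_depth=2)
        found = {s.knockouts: (s.growth, s.product_rate)
                 for s in iterative_knockout_search(model, cfg)}

        ref = reference_state(model)
        mu = ref.objective_value
        p0 = ref.get("EX_Q_e", 0.0)

        def phenotype(genes):
            sol = moma(knockout(model, set(genes)), ref)
            if not sol.optimal:
                return 0.0, 0.0
            return max(sol.fluxes.objective_value, 0.0), sol.fluxes.get("EX_Q_e", 0.0)

        def improved(p_new, p_parent):
            if p_new - p_parent < cfg.min_absolute_gain:
                return False
            return (p_new - p_parent) / max(p_parent, cfg.min_absolute_gain) \
                >= cfg.improvement_threshold

        expected = {}
        round1 = {}
        for g in model.genes:
            growth, product = phenotype((g,))
            if growth > 1e-6 and improved(product, p0):
                expected[(g,)] = (growth, product)
                if growth / mu >= 1 - cfg.growth_drop_cutoff:
                    round1[(g,)] = product
        for (g1,), p_parent in round1.items():
            for g2 in model.genes:
                if g2 == g1:
                    continue
                growth, product = phenotype((g1, g2))
                if growth > 1e-6 and improved(product, p_parent):
                    expected[(g1, g2)] = (growth, product)

        assert set(found) == set(expected)
        for kos, (growth, product) in expected.items():
            assert found[kos][0] == pytest.approx(growth, abs=1e-5)
            assert found[kos][1] == pytest.approx(product, abs=1e-5)

    def test_native_producer_has_an_ha_raising_deletion(self, aerobic_native):
        """At least one single deletion redirects flux into the HA branch
        (the growth-HA tradeoff: product up, growth down)."""
        cfg = SearchConfig(product_reaction="EX_ha_e", max_depth=1)
        strategies = iterative_knockout_search(aerobic_native, cfg)
        assert strategies
        mu = fba(aerobic_native).objective_value
        ref_ha = reference_state(aerobic_native).get("EX_ha_e", 0.0)
        for s in strategies:
            assert s.product_rate > ref_ha + 1e-4
            assert s.growth < mu - 1e-6
            assert s.round == len(s.knockouts) == 1

    def test_results_are_deterministic(self, aerobic_native):
        cfg = SearchConfig(product_reaction="EX_ha_e", max_depth=1)
        a = iterative_knockout_search(aerobic_native, cfg)
        b = iterative_knockout_search(aerobic_native, cfg)
        assert [(s.knockouts, s.growth, s.product_rate) for s in a] == [
            (s.knockouts, s.growth, s.product_rate) for s in b
        ]

    def test_reported_phenotypes_reproducible_by_independent_calls(
        self, aerobic_native
    ):
        cfg = SearchConfig(product_reaction="EX_ha_e", max_depth=1)
        strategies = iterative_knockout_search(aerobic_native, cfg)
        ref = reference_state(aerobic_native)
        for s in strategies[:3]:
            sol = moma(knockout(aerobic_native, set(s.knockouts)), ref)
            assert sol.fluxes.objective_value == pytest.approx(s.growth, abs=1e-6)
            assert sol.fluxes["EX_ha_e"] == pytest.approx(s.product_rate, abs=1e-6)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SearchConfig(product_reaction="EX_ha_e", growth_drop_cutoff=1.5)
        with pytest.raises(ValueError):
            SearchConfig(product_reaction="EX_ha_e", max_depth=0)


class TestAlternateOptima:
    def test_unique_optimum_gives_identical_samples(self):
        model = build_chain_model()
        cfg = AltOptimaConfig(n_samples=5, growth_fraction=1.0, seed=1)
        samples = sample_alternate_optima(model, "EX_A_e", cfg, "minimize")
        first = samples[0].fluxes
        for s in samples[1:]:
            for rid, v in first.items():
                assert s.fluxes[rid] == pytest.approx(v, abs=1e-8)

    def test_samples_satisfy_growth_and_objective_constraints(
        self, recombinant_model
    ):
        mu = fba(recombinant_model).objective_value
        cfg = AltOptimaConfig(n_samples=50, growth_fraction=0.95, seed=11)
        for direction in ("maximize", "minimize"):
            samples = sample_alternate_optima(
                recombinant_model, "EX_ha_e", cfg, direction
            )
            assert len(samples) == 50
            constrained = fix_growth_fraction(recombinant_model, 0.95)
            extreme = fba(constrained, "EX_ha_e", direction).objective_value
            for s in samples:
                assert s.fluxes["BIOMASS"] >= 0.95 * mu - 1e-6
                assert abs(s.fluxes["EX_ha_e"] - extreme) <= 1e-5

    def test_sample_ranges_contain_the_single_fba_vertex(self, recombinant_model):
        cfg = AltOptimaConfig(n_samples=40, growth_fraction=0.95, seed=5)
        samples = sample_alternate_optima(recombinant_model, "EX_ha_e", cfg)
        vertex = fba(fix_growth_fraction(recombinant_model, 0.95), "EX_ha_e")
        for rid in ("EX_ha_e", "BIOMASS", "HAS"):
            values = [s.fluxes[rid] for s in samples]
            assert min(values) - 1e-5 <= vertex[rid] <= max(values) + 1e-5

    def test_identical_seed_reproduces_samples(self, recombinant_model):
        cfg = AltOptimaConfig(n_samples=10, seed=42)
        a = sample_alternate_optima(recombinant_model, "EX_ha_e", cfg)
        b = sample_alternate_optima(recombinant_model, "EX_ha_e", cfg)
        for s1, s2 in zip(a, b):
            assert s1.fluxes == s2.fluxes


class TestRegulationTargets:
    @staticmethod
    def fake(fluxes):
        return FluxDistribution(fluxes, 0.0, "optimal")

    def test_identical_sample_sets_give_no_targets(self):
        s = [self.fake({"R": 1.0, "Q": 2.0})] * 3
        assert regulation_targets(s, list(s)) == []

    def test_hand_built_separation_reported(self):
        mx = [self.fake({"R": 5.0, "Q": 1.0}), self.fake({"R": 6.0, "Q": 3.0})]
        mn = [self.fake({"R": 1.0, "Q": 2.0}), self.fake({"R": 2.0, "Q": 2.5})]
        targets = regulation_targets(mx, mn)
        assert [(t.reaction, t.direction) for t in targets] == [("R", "up")]
        assert targets[0].separation == pytest.approx(3.0)

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ValueError):
            regulation_targets([self.fake({"R": 1.0})], [self.fake({"Q": 1.0})])

    def test_ha_synthase_nominated_up_on_recombinant(self, recombinant_model):
        cfg = AltOptimaConfig(n_samples=30, growth_fraction=0.95, seed=7)
        mx = sample_alternate_optima(recombinant_model, "EX_ha_e", cfg, "maximize")
        mn = sample_alternate_optima(recombinant_model, "EX_ha_e", cfg, "minimize")
        targets = regulation_targets(mx, mn)
        assert ("HAS", "up") in [(t.reaction, t.direction) for t in targets]

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            RegulationTarget("R", "up", 0.0)
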