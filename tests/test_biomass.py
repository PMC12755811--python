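"""Biomass construction: sequence-derived compositions, maintenance
energetics, and the HA pathway cost accounting."""

import numpy as np
import pytest

from hyaflux import (
    MacromoleculeComposition,
    MaintenanceParameters,
    apply_medium,
    assemble_biomass,
    dna_composition,
    fba,
    ha_pathway,
    ngam_from_maintenance_uptake,
    ngam_reaction,
    protein_composition,
    check_balance,
)
from hyaflux.biomass import net_mass_consumed, rna_composition
from hyaflux.synth import make_native_model, native_cdm_medium


class TestDnaComposition:
    def test_equimolar_sequence(self):
        comp = dna_composition("ATGC")
        assert all(v == pytest.approx(0.25) for v in comp.values())

    def test_single_strand_counts_both_strands(self):
        comp = dna_composition("AAAA")
        assert comp["dAMP"] == pytest.approx(0.5)
        assert comp["dTMP"] == pytest.approx(0.5)
        assert comp["dCMP"] == 0.0

    def test_random_kilobase_matches_counting_oracle(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        comp = dna_composition(seq)
        # independent tally: count bases on both strands explicitly
        complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
        both = seq + "".join(complement[b] for b in seq)
        for base, key in [("A", "dAMP"), ("T", "dTMP"), ("C", "dCMP"), ("G", "dGMP")]:
            assert comp[key] == pytest.approx(both.count(base) / len(both))

    def test_ambiguous_bases_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped 2"):
            comp = dna_composition("ATNNGC")
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dna_composition("NNN")

    def test_fasta_input(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\nATGC\n>chr2\nGCTA\n")
        comp = dna_composition(str(fasta))
        assert all(v == pytest.approx(0.25) for v in comp.values())


class TestProteinComposition:
    def test_single_cds(self):
        comp = protein_composition("ATGAAA")
        assert comp == {"M": 0.5, "K": 0.5}

    def test_codon_table_input(self):
        assert protein_composition({"GGT": 12}) == {"G": 1.0}
        assert protein_composition({"GGU": 3, "UAA": 5}) == {"G": 1.0}

    def test_stop_codon_dropped_at_end(self):
        comp = protein_composition("ATGAAATAA")
        assert comp == {"M": 0.5, "K": 0.5}

    def test_internal_stop_skips_sequence_with_warning(self):
        with pytest.warns(UserWarning, match="internal stop"):
            comp = protein_composition(["ATGTAAAAA", "ATGGGT"])
        assert comp == {"M": 0.5, "G": 0.5}

    def test_length_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError):
            protein_composition("ATGA")

    def test_random_cds_set_matches_backtranslation_oracle(self):
        """Generate proteins first, back-translate with hand-listed synonymous
        codons, and require the tallied composition to match exactly."""
        codons = {"M": ["ATG"], "K": ["AAA", "AAG"], "G": ["GGT", "GGC"],
                  "L": ["CTG", "TTA"], "S": ["TCT", "AGC"], "W": ["TGG"]}
        rng = np.random.default_rng(99)
        counts = {aa: 0 for aa in codons}
        cds_set = []
        for _ in range(10):
            protein = rng.choice(list(codons), size=rng.integers(5, 30))
            for aa in protein:
                counts[aa] += 1
            cds_set.append("".join(rng.choice(codons[aa]) for aa in protein))
        comp = protein_composition(cds_set)
        total = sum(counts.values())
        for aa, n in counts.items():
            assert comp.get(aa, 0.0) == pytest.approx(n / total)


class TestAssembleBiomass:
    protein_only = MacromoleculeComposition(
        protein={"A": 0.5, "K": 0.5}, mass_fractions={"protein": 1.0}
    )

    def test_gam_atp_coefficient_is_default(self):
        rxn = assemble_biomass(self.protein_only, MaintenanceParameters())
        assert rxn.stoichiometry["atp_c"] == pytest.approx(-39.4)
        assert rxn.stoichiometry["adp_c"] == pytest.approx(39.4)
        assert rxn.kind == "pseudo"

    def test_protein_only_composition_consumes_only_amino_acids_and_gam(self):
        rxn = assemble_biomass(self.protein_only, MaintenanceParameters(gam=0.0))
        consumed = {m for m, c in rxn.stoichiometry.items() if c < 0}
        assert consumed == {"ala__L_c", "lys__L_c"}

    def test_mass_accounting_closes_to_mass_fraction_sum(self, native_model):
        """Net mass consumed per gram biomass equals the composition's mass
        within 1% (polymerization water is released, GAM is mass-neutral)."""
        rxn = native_model.reaction("BIOMASS")
        net = net_mass_consumed(rxn, native_model)
        assert net == pytest.approx(0.85, rel=0.01)  # protein+rna+wall

    def test_fraction_sums_validated(self):
        bad = MacromoleculeComposition(
            protein={"A": 0.6, "K": 0.5}, mass_fractions={"protein": 1.0}
        )
        with pytest.raises(ValueError):
            assemble_biomass(bad, MaintenanceParameters())
        too_heavy = MacromoleculeComposition(
            protein={"A": 1.0}, mass_fractions={"protein": 1.2}
        )
        with pytest.raises(ValueError):
            assemble_biomass(too_heavy, MaintenanceParameters())

    def test_rna_fractions_from_sequence(self):
        comp = rna_composition("AUGC")
        assert all(v == pytest.approx(0.25) for v in comp.values())


class TestNgam:
    def test_reaction_lower_bound_carries_ngam(self):
        rxn = ngam_reaction(MaintenanceParameters(ngam=3.5))
        assert rxn.lower_bound == 3.5
        assert rxn.stoichiometry["atp_c"] == -1.0

    def test_zero_ngam_has_no_effect_on_growth(self):
        from hyaflux.synth import SyntheticModelParams

        relaxed = make_native_model(SyntheticModelParams(ngam=0.0))
        base = make_native_model(SyntheticModelParams(ngam=1.0))
        assert fba(relaxed).objective_value >= fba(base).objective_value

    def test_helper_is_a_product(self):
        assert ngam_from_maintenance_uptake(1.0, 2.0) == 2.0
        assert ngam_from_maintenance_uptake(0.5, 26.0) == 13.0

    def test_growth_strictly_decreases_as_ngam_increases(self):
        from hyaflux.synth import SyntheticModelParams

        growths = [
            fba(make_native_model(SyntheticModelParams(ngam=n))).objective_value
            for n in (0.0, 5.0, 10.0, 20.0)
        ]
        assert all(b < a for a, b in zip(growths, growths[1:]))


class TestHaPathway:
    def test_default_pathway_costs_five_atp_one_accoa_two_nad(self, native_model):
        _, _, report = ha_pathway(native_model)
        assert report.atp_equivalents == pytest.approx(5.0, abs=1e-6)
        assert report.acetyl_coa == pytest.approx(1.0, abs=1e-6)
        assert report.nad == pytest.approx(2.0, abs=1e-6)

    def test_condensation_is_elementally_balanced(self, native_model):
        condensation, _, _ = ha_pathway(native_model)
        report = check_balance(condensation, native_model)
        assert report.is_balanced, report

    def test_cost_matches_hand_tallied_route(self, native_model):
        """Independent oracle: the known route multiplicities, summed by hand.

        Per disaccharide: 2 hexokinase + 1 glutamine synthetase ATP, 2 UTP
        regenerated by NDK (2 more ATP), 1 acetyl-CoA at the acetyltransferase,
        2 NAD at the UDP-glucose dehydrogenase.
        """
        route_flux = {
            "HEX1": 2, "PGI": 1, "PGMT": 1, "GALU": 1, "UDPGDH": 1,
            "GF6PTA": 1, "GLNS": 1, "GAMAT": 1, "PGAMT": 1, "UAGDP": 1,
            "HAS": 1, "NDK1": 2,
        }
        consumed = {"atp_c": 0.0, "accoa_c": 0.0, "nad_c": 0.0}
        for rid, mult in route_flux.items():
            for met, coef in native_model.reaction(rid).stoichiometry.items():
                if met in consumed:
                    consumed[met] -= coef * mult
        _, _, report = ha_pathway(native_model)
        assert report.atp_equivalents == pytest.approx(consumed["atp_c"])
        assert report.acetyl_coa == pytest.approx(consumed["accoa_c"])
        assert report.nad == pytest.approx(consumed["nad_c"])

    def test_missing_precursor_branch_rejected(self):
        from conftest import build_chain_model

        with pytest.raises(ValueError, match="udpglcur"):
            ha_pathway(build_chain_model())

    def test_ha_flux_equals_condensation_flux(self, aerobic_native):
        """Stoichiometric coupling: exported HA equals UDP-GlcA consumed by
        the synthase in any flux solution."""
        from hyaflux import fix_growth_fraction

        sol = fba(fix_growth_fraction(aerobic_native, 0.95), "EX_ha_e")
        assert sol.objective_value > 0.01
        assert sol["HAS"] == pytest.approx(sol["EX_ha_e"], abs=1e-6)
        udpglcur_used = -sum(
            coef * sol[rid]
            for rid in ("HAS",)
            for met, coef in aerobic_native.reaction(rid).stoichiometry.items()
            if met == "udpglcur_c"
        )
        assert udpglcur_used == pytest.approx(sol["EX_ha_e"], abs=1e-6)
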