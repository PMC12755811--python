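"""Biomass and product pseudo-reaction construction.

The biomass objective function consumes macromolecular precursors in
mmol.gDCW^-1 amounts derived from sequence-based compositions (DNA from the
genome with double-strand base pairing, protein from codon usage of coding
sequences) plus a growth-associated maintenance (GAM) ATP hydrolysis term.
A separate non-growth-associated maintenance (NGAM) reaction carries a fixed
ATP-hydrolysis lower bound.

The hyaluronic-acid (HA) branch helper adds the HA condensation
pseudo-reaction (UDP-glucuronate + UDP-N-acetylglucosamine -> HA disaccharide
unit + 2 UDP) and its exchange, and produces a cost report tracing the
elementary route from glucose: per disaccharide the default pathway consumes
5 ATP equivalents (two hexose phosphorylations, two UTP regenerated through
nucleoside-diphosphate kinase, and one ATP for glutamine regeneration), one
acetyl-CoA and two NAD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.optimize import linprog

from .gpr import GprRule
from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    formula_weight,
    parse_formula,
)

__all__ = [
    "MacromoleculeComposition",
    "MaintenanceParameters",
    "HaCostReport",
    "dna_composition",
    "protein_composition",
    "assemble_biomass",
    "ngam_reaction",
    "ngam_from_maintenance_uptake",
    "ha_pathway",
    "net_mass_consumed",
    "DEFAULT_GAM",
]

#: Growth-associated maintenance default, mmol ATP per gDCW of biomass formed.
DEFAULT_GAM = 39.4

WATER_MW = formula_weight("H2O")

# Free-monomer formulas (neutral species) used for molecular weights.
AMINO_ACID_FORMULAS = {
    "A": "C3H7NO2", "R": "C6H14N4O2", "N": "C4H8N2O3", "D": "C4H7NO4",
    "C": "C3H7NO2S", "Q": "C5H10N2O3", "E": "C5H9NO4", "G": "C2H5NO2",
    "H": "C6H9N3O2", "I": "C6H13NO2", "L": "C6H13NO2", "K": "C6H14N2O2",
    "M": "C5H11NO2S", "F": "C9H11NO2", "P": "C5H9NO2", "S": "C3H7NO3",
    "T": "C4H9NO3", "W": "C11H12N2O2", "Y": "C9H11NO3", "V": "C5H11NO2",
}
DNA_FORMULAS = {
    "dAMP": "C10H14N5O6P", "dTMP": "C10H15N2O8P",
    "dCMP": "C9H14N3O7P", "dGMP": "C10H14N5O7P",
}
RNA_FORMULAS = {
    "AMP": "C10H14N5O7P", "UMP": "C9H13N2O9P",
    "CMP": "C9H14N3O8P", "GMP": "C10H14N5O8P",
}

# Default metabolite ids for precursors (BIGG-style, cytosolic).
AMINO_ACID_MET_IDS = {
    "A": "ala__L_c", "R": "arg__L_c", "N": "asn__L_c", "D": "asp__L_c",
    "C": "cys__L_c", "Q": "gln__L_c", "E": "glu__L_c", "G": "gly_c",
    "H": "his__L_c", "I": "ile__L_c", "L": "leu__L_c", "K": "lys__L_c",
    "M": "met__L_c", "F": "phe__L_c", "P": "pro__L_c", "S": "ser__L_c",
    "T": "thr__L_c", "W": "trp__L_c", "Y": "tyr__L_c", "V": "val__L_c",
}
DNA_MET_IDS = {"dAMP": "damp_c", "dTMP": "dtmp_c", "dCMP": "dcmp_c", "dGMP": "dgmp_c"}
RNA_MET_IDS = {"AMP": "amp_c", "UMP": "ump_c", "CMP": "cmp_c", "GMP": "gmp_c"}


def _sequences(source) -> list:
    """Accept a FASTA path, a sequence string, or an iterable of either."""
    if isinstance(source, (str, Path)):
        try:
            is_file = Path(str(source)).exists()
        except OSError:  # raw sequence longer than a legal path name
            is_file = False
        if is_file:
            return [str(rec.seq).upper() for rec in SeqIO.parse(str(source), "fasta")]
        return [str(source).upper()]
    return [str(getattr(s, "seq", s)).upper() for s in source]


def dna_composition(genome) -> dict:
    """Molar fractions of dAMP/dTMP/dCMP/dGMP from a genome sequence.

    The genome is counted double-stranded (A pairs with T, G with C), so
    complementary deoxyribonucleotides always have equal fractions.
    Ambiguous bases are skipped with a warning.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    skipped = 0
    for seq in _sequences(genome):
        for base in seq:
            if base in counts:
                counts[base] += 1
            else:
                skipped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty genome sequence")
    if skipped:
        warnings.warn(f"skipped {skipped} ambiguous bases in DNA composition")
    both = 2 * total  # both strands
    return {
        "dAMP": (counts["A"] + counts["T"]) / both,
        "dTMP": (counts["A"] + counts["T"]) / both,
        "dCMP": (counts["C"] + counts["G"]) / both,
        "dGMP": (counts["C"] + counts["G"]) / both,
    }


def rna_composition(transcriptome) -> dict:
    """Molar fractions of AMP/UMP/CMP/GMP from whole-cell RNA sequence(s)."""
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    skipped = 0
    for seq in _sequences(transcriptome):
        for base in seq.replace("T", "U"):
            if base in counts:
                counts[base] += 1
            else:
                skipped += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty RNA sequence")
    if skipped:
        warnings.warn(f"skipped {skipped} ambiguous bases in RNA composition")
    return {
        "AMP": counts["A"] / total,
        "UMP": counts["U"] / total,
        "CMP": counts["C"] / total,
        "GMP": counts["G"] / total,
    }


def protein_composition(cds_or_codon_table) -> dict:
    """Amino-acid molar fractions from coding sequences or a codon-count table.

    Coding sequences are translated with the standard genetic code; stop
    codons are dropped, and a CDS containing an internal stop is skipped with
    a warning.  Alternatively a 64-entry codon -> count table may be given.
    Keys of the result are one-letter amino-acid codes.
    """
    counts: dict = {}
    if isinstance(cds_or_codon_table, dict):
        for codon, n in cds_or_codon_table.items():
            codon = codon.upper().replace("U", "T")
            if len(codon) != 3 or any(b not in "ACGT" for b in codon):
                raise ValueError(f"invalid codon {codon!r}")
            aa = str(Seq(codon).translate())
            if aa == "*":
                continue
            counts[aa] = counts.get(aa, 0) + n
    else:
        for i, seq in enumerate(_sequences(cds_or_codon_table)):
            if len(seq) % 3:
                raise ValueError(f"CDS #{i} length {len(seq)} not divisible by 3")
            protein = str(Seq(seq).translate())
            core = protein[:-1] if protein.endswith("*") else protein
            if "*" in core:
                warnings.warn(f"internal stop codon in CDS #{i}; sequence skipped")
                continue
            for aa in core:
                if aa not in AMINO_ACID_FORMULAS:
                    raise ValueError(f"cannot translate CDS #{i}: residue {aa!r}")
                counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no codons to tally")
    return {aa: n / total for aa, n in counts.items()}


def _check_fractions(name: str, fractions: dict, tol: float = 1e-9) -> None:
    if fractions and abs(sum(fractions.values()) - 1.0) > tol:
        raise ValueError(f"{name} molar fractions sum to {sum(fractions.values())}, not 1")


@dataclass
class MacromoleculeComposition:
    """Macromolecular make-up of one gram of dry cell weight.

    ``mass_fractions`` maps macromolecule name (protein / rna / dna / any
    extra pool such as cell_wall) to g per gDCW; the per-macromolecule dicts
    give monomer molar fractions, each summing to 1.  ``extra`` holds
    template pools (monomer metabolite id -> molar fraction) for components
    not derived from sequence data.
    """

    protein: dict = field(default_factory=dict)
    rna: dict = field(default_factory=dict)
    dna: dict = field(default_factory=dict)
    mass_fractions: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # name -> {met_id: molar fraction}

    def validate(self) -> None:
        _check_fractions("protein", self.protein)
        _check_fractions("rna", self.rna)
        _check_fractions("dna", self.dna)
        for name, pool in self.extra.items():
            _check_fractions(name, pool)
        total = sum(self.mass_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError(f"mass fractions sum to {total} > 1")
        for name in self.mass_fractions:
            if name not in ("protein", "rna", "dna") and name not in self.extra:
                raise ValueError(f"mass fraction for unknown macromolecule {name!r}")


@dataclass
class MaintenanceParameters:
    """GAM (mmol ATP per gDCW formed) and NGAM (mmol ATP.gDCW^-1.h^-1)."""

    gam: float = DEFAULT_GAM
    ngam: float = 0.0

    def __post_init__(self):
        if self.gam < 0 or self.ngam < 0:
            raise ValueError("maintenance parameters must be non-negative")


def _polymer_coefficients(fractions: dict, formulas: dict, mass_fraction: float) -> tuple:
    """mmol monomer per gDCW for one macromolecule, plus water released.

    Uses residue weights (monomer MW minus one water per polymerized bond) so
    the polymer mass equals the mass fraction exactly.
    """
    residue = {
        k: formula_weight(formulas[k]) - WATER_MW for k in fractions
    }
    mean_residue = sum(fractions[k] * residue[k] for k in fractions)
    coeffs = {
        k: 1000.0 * mass_fraction * fractions[k] / mean_residue for k in fractions
    }
    water = sum(coeffs.values())
    return coeffs, water


def assemble_biomass(
    comp: MacromoleculeComposition,
    maint: MaintenanceParameters,
    reaction_id: str = "BIOMASS",
    extra_monomer_weights: dict | None = None,
) -> Reaction:
    """Build the biomass pseudo-reaction (flux = growth rate, h^-1).

    Precursors are consumed in mmol.gDCW^-1 amounts; polymerization water is
    released; the GAM term hydrolyzes ``maint.gam`` mmol ATP per gram of
    biomass formed.  ``extra_monomer_weights`` supplies molecular weights
    (g/mol) for monomers of template pools in ``comp.extra``.
    """
    comp.validate()
    stoich: dict = {}

    def consume(coeffs: dict, met_ids: dict):
        for key, c in coeffs.items():
            met = met_ids.get(key, key)
            stoich[met] = stoich.get(met, 0.0) - c

    water_released = 0.0
    for name, frac in comp.mass_fractions.items():
        if frac == 0:
            continue
        if name == "protein":
            coeffs, water = _polymer_coefficients(comp.protein, AMINO_ACID_FORMULAS, frac)
            consume(coeffs, AMINO_ACID_MET_IDS)
        elif name == "rna":
            coeffs, water = _polymer_coefficients(comp.rna, RNA_FORMULAS, frac)
            consume(coeffs, RNA_MET_IDS)
        elif name == "dna":
            coeffs, water = _polymer_coefficients(comp.dna, DNA_FORMULAS, frac)
            consume(coeffs, DNA_MET_IDS)
        else:
            pool = comp.extra[name]
            weights = {m: (extra_monomer_weights or {}).get(m) for m in pool}
            missing = [m for m, w in weights.items() if w is None]
            if missing:
                raise ValueError(
                    f"no molecular weight for template monomers {missing} of {name!r}"
                )
            coeffs, water = _template_coefficients(pool, weights, frac)
            consume(coeffs, {})
        water_released += water

    # GAM: gam x (atp + h2o -> adp + pi + h)
    gam = maint.gam
    stoich["atp_c"] = stoich.get("atp_c", 0.0) - gam
    stoich["h2o_c"] = stoich.get("h2o_c", 0.0) - gam + water_released
    stoich["adp_c"] = stoich.get("adp_c", 0.0) + gam
    stoich["pi_c"] = stoich.get("pi_c", 0.0) + gam
    stoich["h_c"] = stoich.get("h_c", 0.0) + gam
    # 6 decimals (1 nmol.gDCW^-1) keeps coefficients exact across text formats
    stoich = {m: round(c, 6) for m, c in stoich.items() if round(c, 6) != 0.0}
    return Reaction(
        id=reaction_id,
        name="biomass formation",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        gpr=GprRule(),
        kind="pseudo",
        subsystem="biomass",
    )


def _template_coefficients(pool: dict, weights: dict, mass_fraction: float) -> tuple:
    residue = {m: weights[m] - WATER_MW for m in pool}
    mean_residue = sum(pool[m] * residue[m] for m in pool)
    coeffs = {m: 1000.0 * mass_fraction * pool[m] / mean_residue for m in pool}
    return coeffs, sum(coeffs.values())


def ngam_reaction(
    maint: MaintenanceParameters, reaction_id: str = "ATPM"
) -> Reaction:
    """Non-growth maintenance: ATP hydrolysis with a fixed lower bound.

    The lower bound forces at least ``ngam`` mmol ATP.gDCW^-1.h^-1 of
    hydrolysis regardless of growth.
    """
    return Reaction(
        id=reaction_id,
        name="ATP maintenance requirement",
        stoichiometry={
            "atp_c": -1.0, "h2o_c": -1.0,
            "adp_c": 1.0, "pi_c": 1.0, "h_c": 1.0,
        },
        lower_bound=maint.ngam,
        upper_bound=1000.0,
        kind="pseudo",
        subsystem="maintenance",
    )


def ngam_from_maintenance_uptake(q_glc_maintenance: float, atp_yield: float) -> float:
    """NGAM from the glucose uptake observed at zero growth times the ATP yield."""
    return q_glc_maintenance * atp_yield


# -- HA pathway ---------------------------------------------------------------

#: HA disaccharide unit (glucuronate-N-acetylglucosamine polymer residue anion).
HA_UNIT_FORMULA = "C14H20NO11"
HA_UNIT_CHARGE = -1

#: Species treated as currency (left unbalanced) when tracing the HA route.
_CURRENCY = {
    "atp_c", "adp_c", "amp_c", "nad_c", "nadh_c", "nadp_c", "nadph_c",
    "accoa_c", "coa_c", "pi_c", "ppi_c", "h_c", "h2o_c", "co2_c", "nh4_c",
    "glc__D_c",
}

#: Non-branch reactions allowed in the route (glucose entry, glutamine and
#: UTP regeneration); UTP/UDP are balanced within the route so every
#: phosphoanhydride bond is funneled to ATP.
DEFAULT_SUPPORT_REACTIONS = ("HEX1", "PGI", "GLNS", "NDK1")


@dataclass
class HaCostReport:
    """Net cofactor cost of one HA disaccharide unit made from glucose."""

    atp_equivalents: float
    acetyl_coa: float
    nad: float
    route_fluxes: dict = field(default_factory=dict)


def _route_cost(model: MetabolicModel, route: list, target: str = "ha_c") -> HaCostReport:
    mets = sorted(
        {m for r in route for m in r.stoichiometry} - _CURRENCY
    )
    if target not in mets:
        raise ValueError(f"route does not produce {target}")
    A = np.zeros((len(mets), len(route)))
    pos = {m: i for i, m in enumerate(mets)}
    for j, r in enumerate(route):
        for m, c in r.stoichiometry.items():
            if m in pos:
                A[pos[m], j] = c
    b = np.zeros(len(mets))
    b[pos[target]] = 1.0
    res = linprog(
        np.ones(len(route)), A_eq=A, b_eq=b,
        bounds=[(0, None)] * len(route), method="highs",
    )
    if res.status != 0:
        raise ValueError("HA route is not stoichiometrically closable from glucose")
    v = res.x

    def net_consumption(met: str) -> float:
        return float(
            -sum(r.stoichiometry.get(met, 0.0) * v[j] for j, r in enumerate(route))
        )

    return HaCostReport(
        atp_equivalents=net_consumption("atp_c"),
        acetyl_coa=net_consumption("accoa_c"),
        nad=net_consumption("nad_c"),
        route_fluxes={r.id: float(v[j]) for j, r in enumerate(route) if v[j] > 1e-9},
    )


def ha_pathway(
    model: MetabolicModel,
    support_reactions=DEFAULT_SUPPORT_REACTIONS,
    add_missing: bool = True,
) -> tuple:
    """HA condensation + exchange reactions and the pathway cost report.

    Requires the UDP-glucuronate and UDP-N-acetylglucosamine branches in the
    model (subsystem tag ``"ha_pathway"``).  When missing and ``add_missing``,
    the condensation (1 UDP-GlcA + 1 UDP-GlcNAc -> HA unit + 2 UDP + 2 H+),
    HA export and HA exchange reactions are added to the model in place.

    Returns ``(condensation_reaction, exchange_reaction, cost_report)``.
    """
    met_ids = set(model.metabolite_ids)
    for required in ("udpglcur_c", "uacgam_c"):
        if required not in met_ids:
            raise ValueError(f"HA precursor branch incomplete: missing {required}")

    existing = {r.id for r in model.reactions}
    if "HAS" not in existing:
        if not add_missing:
            raise ValueError("model lacks the HA condensation reaction")
        for mid, comp in (("ha_c", "c"), ("ha_e", "e")):
            if mid not in met_ids:
                model.metabolites.append(
                    Metabolite(mid, "hyaluronan disaccharide unit",
                               HA_UNIT_FORMULA, HA_UNIT_CHARGE, comp)
                )
        model.reactions.append(
            Reaction(
                id="HAS",
                name="hyaluronan synthase",
                stoichiometry={
                    "udpglcur_c": -1, "uacgam_c": -1,
                    "ha_c": 1, "udp_c": 2, "h_c": 2,
                },
                lower_bound=0.0,
                kind="internal",
                subsystem="ha_pathway",
            )
        )
        model.reactions.append(
            Reaction(
                id="HAt", name="HA export",
                stoichiometry={"ha_c": -1, "ha_e": 1},
                lower_bound=0.0, kind="transport", subsystem="ha_pathway",
            )
        )
        model.reactions.append(
            Reaction(
                id="EX_ha_e", name="HA exchange",
                stoichiometry={"ha_e": -1},
                lower_bound=0.0, kind="exchange", subsystem="ha_pathway",
            )
        )
    condensation = model.reaction("HAS")
    exchange = model.reaction("EX_ha_e")

    route = [r for r in model.reactions if r.subsystem == "ha_pathway" and r.kind == "internal"]
    rxn_ids = {r.id for r in model.reactions}
    route += [model.reaction(rid) for rid in support_reactions if rid in rxn_ids]
    report = _route_cost(model, route)
    return condensation, exchange, report


def net_mass_consumed(reaction: Reaction, metabolite_table) -> float:
    """Net mass (g) consumed per unit flux, from metabolite formulas.

    For a biomass reaction built by :func:`assemble_biomass` this equals the
    sum of the macromolecule mass fractions (coefficients are mmol, so the
    result is in g per gDCW of biomass).
    """
    if isinstance(metabolite_table, MetabolicModel):
        metabolite_table = {m.id: m for m in metabolite_table.metabolites}
    net = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        met = metabolite_table[met_id]
        if met.formula is None:
            raise ValueError(f"metabolite {met_id} lacks a formula")
        net -= coef * formula_weight(met.formula) / 1000.0
    return net
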