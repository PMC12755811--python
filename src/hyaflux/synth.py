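"""Deterministic generators for a native/recombinant toy-model pair.

Two small genome-scale-style networks with real biochemistry provide a
download-free test surface for the whole pipeline:

* the **native producer** — a fastidious, facultatively anaerobic lactic
  fermenter: EMP glycolysis, homolactic fermentation plus pyruvate-formate
  lyase, a non-phosphorylating NADP-GAPDH as NADPH source, non-oxidative (but
  no oxidative) pentose-phosphate pathway, a truncated TCA branch to
  2-oxoglutarate, amino-acid auxotrophies, nucleobase salvage, an
  NADH-oxidase oxygen valve, and the chromosomal HA operon;

* the **recombinant producer** — a prototrophic aerobe: oxidative PPP
  (glucose-6-phosphate dehydrogenase, "zwf"), full TCA cycle with lumped
  oxidative phosphorylation, de novo amino-acid and nucleotide biosynthesis,
  and the same HA branch carried as a heterologous operon.

Every internal reaction is elementally and charge balanced: lumped
biosynthesis reactions are written with exact C/N/P/S bookkeeping and their
H/O/charge residuals are closed with water and protons by a helper that
raises if any heavier element is off.  Topology is fully deterministic; the
seed in the parameters is stored for downstream stochastic steps and does not
perturb construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biomass import (
    MacromoleculeComposition,
    MaintenanceParameters,
    assemble_biomass,
    ngam_reaction,
)
from .gpr import parse_gpr
from .model import (
    Medium,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_medium,
    check_balance,
    formula_weight,
    parse_formula,
)
from .validation import ScreenResult, ScreenRow

__all__ = [
    "SyntheticModelParams",
    "make_native_model",
    "make_recombinant_model",
    "native_cdm_medium",
    "recombinant_minimal_medium",
    "make_validation_fixture",
    "AUXOTROPHY_CANDIDATES",
]

# -- parameters ----------------------------------------------------------------


@dataclass
class SyntheticModelParams:
    """Construction parameters of the toy models.

    ``glucose_uptake`` defaults to the chemostat-derived rates of the two
    organisms (18.56 native, 4.67 recombinant, mmol.gDCW^-1.h^-1) and is used
    when the generator applies its default medium.  ``n_auxotrophies`` picks
    how many of the candidate amino acids (Met, Leu, Arg, Ile, Val, in that
    order) lack a biosynthetic route.
    """

    seed: int = 7
    glucose_uptake: float | None = None
    include_oxidative_ppp: bool = False
    include_full_tca: bool = False
    n_auxotrophies: int = 5
    ngam: float = 1.0
    gam: float = 39.4

    def __post_init__(self):
        if self.glucose_uptake is not None and self.glucose_uptake <= 0:
            raise ValueError("glucose uptake must be positive")
        if not 0 <= self.n_auxotrophies <= 5:
            raise ValueError("n_auxotrophies must be in [0, 5]")


AUXOTROPHY_CANDIDATES = ("met__L", "leu__L", "arg__L", "ile__L", "val__L")

#: Acetate-kinase capacity (mmol.gDCW^-1.h^-1) of the native model's
#: mixed-acid branch, well below the homolactic glycolytic flux.
_ACETATE_KINASE_CAP = 5.0

# -- metabolite catalogue (real formulas, BIGG-style charged species) ----------

_METS = {
    # sugars
    "glc__D": ("D-glucose", "C6H12O6", 0),
    "fru": ("D-fructose", "C6H12O6", 0),
    "sucr": ("sucrose", "C12H22O11", 0),
    "malt": ("maltose", "C12H22O11", 0),
    "lcts": ("lactose", "C12H22O11", 0),
    "gal": ("D-galactose", "C6H12O6", 0),
    # glycolysis / PPP
    "g6p": ("D-glucose 6-phosphate", "C6H11O9P", -2),
    "f6p": ("D-fructose 6-phosphate", "C6H11O9P", -2),
    "fdp": ("D-fructose 1,6-bisphosphate", "C6H10O12P2", -4),
    "dhap": ("dihydroxyacetone phosphate", "C3H5O6P", -2),
    "g3p": ("glyceraldehyde 3-phosphate", "C3H5O6P", -2),
    "13dpg": ("1,3-bisphospho-D-glycerate", "C3H4O10P2", -4),
    "3pg": ("3-phospho-D-glycerate", "C3H4O7P", -3),
    "2pg": ("2-phospho-D-glycerate", "C3H4O7P", -3),
    "pep": ("phosphoenolpyruvate", "C3H2O6P", -3),
    "pyr": ("pyruvate", "C3H3O3", -1),
    "r5p": ("ribose 5-phosphate", "C5H9O8P", -2),
    "ru5p__D": ("ribulose 5-phosphate", "C5H9O8P", -2),
    "xu5p__D": ("xylulose 5-phosphate", "C5H9O8P", -2),
    "s7p": ("sedoheptulose 7-phosphate", "C7H13O10P", -2),
    "e4p": ("erythrose 4-phosphate", "C4H7O7P", -2),
    "prpp": ("5-phospho-alpha-D-ribose 1-diphosphate", "C5H8O14P3", -5),
    # fermentation / TCA
    "lac__D": ("D-lactate", "C3H5O3", -1),
    "for": ("formate", "CHO2", -1),
    "ac": ("acetate", "C2H3O2", -1),
    "actp": ("acetyl phosphate", "C2H3O5P", -2),
    "accoa": ("acetyl-CoA", "C23H34N7O17P3S", -4),
    "coa": ("coenzyme A", "C21H32N7O16P3S", -4),
    "cit": ("citrate", "C6H5O7", -3),
    "icit": ("isocitrate", "C6H5O7", -3),
    "akg": ("2-oxoglutarate", "C5H4O5", -2),
    "succoa": ("succinyl-CoA", "C25H35N7O19P3S", -5),
    "succ": ("succinate", "C4H4O4", -2),
    "fum": ("fumarate", "C4H2O4", -2),
    "mal__L": ("L-malate", "C4H4O5", -2),
    "oaa": ("oxaloacetate", "C4H2O5", -2),
    # energy & redox
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "amp": ("AMP", "C10H12N5O7P", -2),
    "utp": ("UTP", "C9H11N2O15P3", -4),
    "udp": ("UDP", "C9H11N2O12P2", -3),
    "ump": ("UMP", "C9H11N2O9P", -2),
    "nad": ("NAD+", "C21H26N7O14P2", -1),
    "nadh": ("NADH", "C21H27N7O14P2", -2),
    "nadp": ("NADP+", "C21H25N7O17P3", -3),
    "nadph": ("NADPH", "C21H26N7O17P3", -4),
    "pi": ("phosphate", "HO4P", -2),
    "ppi": ("diphosphate", "HO7P2", -3),
    # small inorganics
    "h": ("proton", "H", 1),
    "h2o": ("water", "H2O", 0),
    "co2": ("carbon dioxide", "CO2", 0),
    "o2": ("oxygen", "O2", 0),
    "nh4": ("ammonium", "H4N", 1),
    "h2s": ("hydrogen sulfide", "H2S", 0),
    # nucleobases
    "ade": ("adenine", "C5H5N5", 0),
    "ura": ("uracil", "C4H4N2O2", 0),
    # HA branch
    "g1p": ("D-glucose 1-phosphate", "C6H11O9P", -2),
    "udpg": ("UDP-glucose", "C15H22N2O17P2", -2),
    "udpglcur": ("UDP-glucuronate", "C15H19N2O18P2", -3),
    "gam6p": ("D-glucosamine 6-phosphate", "C6H13NO8P", -1),
    "acgam6p": ("N-acetyl-D-glucosamine 6-phosphate", "C8H14NO9P", -2),
    "acgam1p": ("N-acetyl-D-glucosamine 1-phosphate", "C8H14NO9P", -2),
    "uacgam": ("UDP-N-acetyl-D-glucosamine", "C17H25N3O17P2", -2),
    "ha": ("hyaluronan disaccharide unit", "C14H20NO11", -1),
    # amino acids and intermediates
    "glu__L": ("L-glutamate", "C5H8NO4", -1),
    "gln__L": ("L-glutamine", "C5H10N2O3", 0),
    "ala__L": ("L-alanine", "C3H7NO2", 0),
    "asp__L": ("L-aspartate", "C4H6NO4", -1),
    "asn__L": ("L-asparagine", "C4H8N2O3", 0),
    "ser__L": ("L-serine", "C3H7NO3", 0),
    "gly": ("glycine", "C2H5NO2", 0),
    "thr__L": ("L-threonine", "C4H9NO3", 0),
    "lys__L": ("L-lysine", "C6H15N2O2", 1),
    "met__L": ("L-methionine", "C5H11NO2S", 0),
    "leu__L": ("L-leucine", "C6H13NO2", 0),
    "arg__L": ("L-arginine", "C6H15N4O2", 1),
    "ile__L": ("L-isoleucine", "C6H13NO2", 0),
    "val__L": ("L-valine", "C5H11NO2", 0),
    "aspsa": ("L-aspartate 4-semialdehyde", "C4H7NO3", 0),
}


# -- builder -------------------------------------------------------------------


class _Builder:
    def __init__(self, model_id: str):
        self.model_id = model_id
        self.mets: dict = {}
        self.reactions: list = []

    def met(self, base: str, compartment: str) -> str:
        mid = f"{base}_{compartment}"
        if mid not in self.mets:
            name, formula, charge = _METS[base]
            self.mets[mid] = Metabolite(mid, name, formula, charge, compartment)
        return mid

    def add(
        self,
        rid: str,
        name: str,
        stoich_bases: dict,
        gpr: str = "",
        lb: float = 0.0,
        ub: float = 1000.0,
        kind: str = "internal",
        subsystem: str = "",
        balance: bool = False,
    ) -> Reaction:
        """Add a reaction given base-metabolite stoichiometry (cytosolic
        unless the id already carries a ``_c``/``_e`` suffix)."""
        stoich = {}
        for base, coef in stoich_bases.items():
            if base.endswith("_c") or base.endswith("_e"):
                root, comp = base[:-2], base[-1]
            else:
                root, comp = base, "c"
            stoich[self.met(root, comp)] = stoich.get(self.met(root, comp), 0.0) + coef
        if balance:
            stoich = self._close_residuals(rid, stoich)
        rxn = Reaction(
            id=rid, name=name, stoichiometry=stoich, lower_bound=lb,
            upper_bound=ub, gpr=parse_gpr(gpr), kind=kind, subsystem=subsystem,
        )
        self.reactions.append(rxn)
        return rxn

    def _close_residuals(self, rid: str, stoich: dict) -> dict:
        """Close O with water, then H with protons; any other residual is a bug."""
        res: dict = {}
        charge = 0.0
        for mid, coef in stoich.items():
            met = self.mets[mid]
            for el, n in parse_formula(met.formula).items():
                res[el] = res.get(el, 0.0) + coef * n
            charge += coef * met.charge
        w = -res.get("O", 0.0)
        if w:
            mid = self.met("h2o", "c")
            stoich[mid] = stoich.get(mid, 0.0) + w
            res["H"] = res.get("H", 0.0) + 2 * w
        hh = -res.get("H", 0.0)
        if hh:
            mid = self.met("h", "c")
            stoich[mid] = stoich.get(mid, 0.0) + hh
            charge += hh
        bad = {el: r for el, r in res.items() if el not in ("O", "H") and abs(r) > 1e-9}
        if bad or abs(charge) > 1e-9:
            raise ValueError(f"{rid}: cannot close residuals {bad}, charge {charge}")
        return {m: c for m, c in stoich.items() if c != 0.0}

    def exchange(self, base: str, transport: str = "import", gpr: str = "") -> None:
        """Add an exchange (on the _e species) plus a transport reaction.

        ``transport``: "import" (irreversible e->c), "export" (c->e), or
        "free" (reversible).
        """
        e, c = self.met(base, "e"), self.met(base, "c")
        self.add(f"EX_{base}_e", f"{_METS[base][0]} exchange", {f"{base}_e": -1.0},
                 lb=-1000.0, kind="exchange", subsystem="exchange")
        if transport == "import":
            stoich, lb = {f"{base}_e": -1.0, f"{base}_c": 1.0}, 0.0
        elif transport == "export":
            stoich, lb = {f"{base}_c": -1.0, f"{base}_e": 1.0}, 0.0
        else:
            stoich, lb = {f"{base}_e": -1.0, f"{base}_c": 1.0}, -1000.0
        self.add(f"{base.upper()}t", f"{_METS[base][0]} transport", stoich,
                 gpr=gpr, lb=lb, kind="transport", subsystem="transport")

    def build(self, objective: str, genome_gene_count: int) -> MetabolicModel:
        genes = sorted({g for r in self.reactions for g in r.gpr.genes})
        model = MetabolicModel(
            id=self.model_id,
            metabolites=list(self.mets.values()),
            reactions=self.reactions,
            genes=genes,
            objective_reaction=objective,
            genome_gene_count=genome_gene_count,
        )
        model.validate()
        for rxn in model.reactions:
            report = check_balance(rxn, model)
            if report.status == "unbalanced":
                raise ValueError(
                    f"{rxn.id} unbalanced: {report.element_residuals}, "
                    f"charge {report.charge_residual}"
                )
        return model


# -- shared blocks -------------------------------------------------------------


def _add_glycolysis(b: _Builder) -> None:
    b.add("HEX1", "hexokinase",
          {"glc__D": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1},
          gpr="glk_syn", subsystem="glycolysis")
    b.add("PGI", "glucose-6-phosphate isomerase",
          {"g6p": -1, "f6p": 1}, gpr="pgi_syn", lb=-1000.0, subsystem="glycolysis")
    b.add("PFK", "phosphofructokinase",
          {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1},
          gpr="pfk_syn", subsystem="glycolysis")
    b.add("FBA", "fructose-bisphosphate aldolase",
          {"fdp": -1, "dhap": 1, "g3p": 1}, gpr="fbaA_syn", lb=-1000.0,
          subsystem="glycolysis")
    b.add("TPI", "triose-phosphate isomerase",
          {"dhap": -1, "g3p": 1}, gpr="tpi_syn", lb=-1000.0, subsystem="glycolysis")
    b.add("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
          {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1, "nadh": 1, "h": 1},
          gpr="gap_syn", lb=-1000.0, subsystem="glycolysis")
    b.add("PGK", "phosphoglycerate kinase",
          {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1},
          gpr="pgk_syn", lb=-1000.0, subsystem="glycolysis")
    b.add("PGM", "phosphoglycerate mutase",
          {"3pg": -1, "2pg": 1}, gpr="gpm_syn", lb=-1000.0, subsystem="glycolysis")
    b.add("ENO", "enolase",
          {"2pg": -1, "pep": 1, "h2o": 1}, gpr="eno_syn", lb=-1000.0,
          subsystem="glycolysis")
    b.add("PYK", "pyruvate kinase",
          {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1},
          gpr="pyk_syn", subsystem="glycolysis")


def _add_nonox_ppp(b: _Builder) -> None:
    b.add("RPI", "ribose-5-phosphate isomerase",
          {"r5p": -1, "ru5p__D": 1}, gpr="rpiA_syn", lb=-1000.0, subsystem="ppp")
    b.add("RPE", "ribulose-5-phosphate epimerase",
          {"ru5p__D": -1, "xu5p__D": 1}, gpr="rpe_syn", lb=-1000.0, subsystem="ppp")
    b.add("TKT1", "transketolase 1",
          {"r5p": -1, "xu5p__D": -1, "g3p": 1, "s7p": 1},
          gpr="tktA_syn", lb=-1000.0, subsystem="ppp")
    b.add("TALA", "transaldolase",
          {"g3p": -1, "s7p": -1, "e4p": 1, "f6p": 1},
          gpr="talB_syn", lb=-1000.0, subsystem="ppp")
    b.add("TKT2", "transketolase 2",
          {"e4p": -1, "xu5p__D": -1, "f6p": 1, "g3p": 1},
          gpr="tktA_syn", lb=-1000.0, subsystem="ppp")


def _add_ha_branch(b: _Builder) -> None:
    """The HA operon: UDP-glucuronate and UDP-GlcNAc branches plus synthase."""
    b.add("PGMT", "phosphoglucomutase",
          {"g6p": -1, "g1p": 1}, gpr="pgm_syn", lb=-1000.0, subsystem="ha_pathway")
    b.add("GALU", "UTP-glucose-1-phosphate uridylyltransferase",
          {"g1p": -1, "utp": -1, "h": -1, "udpg": 1, "ppi": 1},
          gpr="hasC_syn", subsystem="ha_pathway")
    b.add("UDPGDH", "UDP-glucose 6-dehydrogenase",
          {"udpg": -1, "nad": -2, "h2o": -1, "udpglcur": 1, "nadh": 2, "h": 3},
          gpr="hasB_syn", subsystem="ha_pathway")
    b.add("GF6PTA", "glutamine-fructose-6-phosphate transaminase",
          {"f6p": -1, "gln__L": -1, "gam6p": 1, "glu__L": 1},
          gpr="glmS_syn", subsystem="ha_pathway")
    b.add("GAMAT", "glucosamine-phosphate N-acetyltransferase",
          {"gam6p": -1, "accoa": -1, "acgam6p": 1, "coa": 1, "h": 1},
          gpr="glmU_syn", subsystem="ha_pathway")
    b.add("PGAMT", "N-acetylglucosamine phosphomutase",
          {"acgam6p": -1, "acgam1p": 1}, gpr="glmM_syn", lb=-1000.0,
          subsystem="ha_pathway")
    b.add("UAGDP", "UDP-N-acetylglucosamine diphosphorylase",
          {"acgam1p": -1, "utp": -1, "h": -1, "uacgam": 1, "ppi": 1},
          gpr="glmU_syn", subsystem="ha_pathway")
    b.add("HAS", "hyaluronan synthase",
          {"udpglcur": -1, "uacgam": -1, "ha": 1, "udp": 2, "h": 2},
          gpr="hasA_syn", subsystem="ha_pathway")
    b.add("EX_ha_e", "HA exchange", {"ha_e": -1.0}, lb=0.0, kind="exchange",
          subsystem="ha_pathway")
    b.add("HAt", "HA export", {"ha_c": -1, "ha_e": 1}, gpr="hasA_syn",
          kind="transport", subsystem="ha_pathway")


def _add_nucleotides(b: _Builder, salvage: bool) -> None:
    b.add("PRPS", "phosphoribosylpyrophosphate synthetase",
          {"r5p": -1, "atp": -1, "prpp": 1, "amp": 1, "h": 1},
          gpr="prs_syn", subsystem="nucleotide")
    if salvage:
        b.add("ADPT", "adenine phosphoribosyltransferase",
              {"ade": -1, "prpp": -1, "amp": 1, "ppi": 1},
              gpr="apt_syn", subsystem="nucleotide")
        b.add("UPPRT", "uracil phosphoribosyltransferase",
              {"ura": -1, "prpp": -1, "ump": 1, "ppi": 1},
              gpr="upp_syn", subsystem="nucleotide")
    # de novo UMP: carbamoyl-phosphate + aspartate -> orotate -> UMP (lumped)
    b.add("PYRSYN", "pyrimidine de novo synthesis (lumped)",
          {"gln__L": -1, "asp__L": -1, "prpp": -1, "atp": -2, "nad": -1,
           "ump": 1, "glu__L": 1, "adp": 2, "pi": 2, "ppi": 1, "nadh": 1},
          gpr="pyrB_syn and pyrD_syn", subsystem="nucleotide", balance=True)
    b.add("UMPK", "UMP kinase",
          {"ump": -1, "atp": -1, "udp": 1, "adp": 1},
          gpr="pyrH_syn", lb=-1000.0, subsystem="nucleotide")
    b.add("NDK1", "nucleoside-diphosphate kinase (UDP)",
          {"udp": -1, "atp": -1, "utp": 1, "adp": 1},
          gpr="ndk_syn", lb=-1000.0, subsystem="nucleotide")
    b.add("ADK1", "adenylate kinase",
          {"amp": -1, "atp": -1, "adp": 2},
          gpr="adk_syn", lb=-1000.0, subsystem="nucleotide")
    b.add("PPA", "inorganic pyrophosphatase",
          {"ppi": -1, "h2o": -1, "pi": 2, "h": 1},
          gpr="ppa_syn", subsystem="nucleotide")


def _add_core_amino_acids(b: _Builder) -> None:
    """Glutamate family, alanine, aspartate, serine, asparagine and the
    aspartate-semialdehyde branch to threonine and lysine."""
    b.add("GLUDy", "glutamate dehydrogenase (NADPH)",
          {"akg": -1, "nh4": -1, "nadph": -1, "h": -1,
           "glu__L": 1, "h2o": 1, "nadp": 1},
          gpr="gdhA_syn", subsystem="amino_acid")
    b.add("GLNS", "glutamine synthetase",
          {"glu__L": -1, "nh4": -1, "atp": -1,
           "gln__L": 1, "adp": 1, "pi": 1, "h": 1},
          gpr="glnA_syn", subsystem="amino_acid")
    b.add("ALATA", "alanine transaminase",
          {"pyr": -1, "glu__L": -1, "ala__L": 1, "akg": 1},
          gpr="alaT_syn or ilvE_syn", subsystem="amino_acid")
    b.add("ASPTA", "aspartate transaminase",
          {"oaa": -1, "glu__L": -1, "asp__L": 1, "akg": 1},
          gpr="aspC_syn", subsystem="amino_acid")
    b.add("SERSYN", "serine synthesis from 3-phosphoglycerate (lumped)",
          {"3pg": -1, "glu__L": -1, "nad": -1, "h2o": -1,
           "ser__L": 1, "akg": 1, "nadh": 1, "pi": 1, "h": 1},
          gpr="serA_syn", subsystem="amino_acid", balance=True)
    b.add("ASNS", "asparagine synthetase",
          {"asp__L": -1, "nh4": -1, "atp": -1,
           "asn__L": 1, "amp": 1, "ppi": 1, "h": 1},
          gpr="asnA_syn", subsystem="amino_acid")
    b.add("ASD", "aspartate kinase + semialdehyde dehydrogenase (lumped)",
          {"asp__L": -1, "atp": -1, "nadph": -1,
           "aspsa": 1, "adp": 1, "pi": 1, "nadp": 1},
          gpr="asd_syn", subsystem="amino_acid", balance=True)
    b.add("THRSYN", "threonine synthesis from aspartate semialdehyde (lumped)",
          {"aspsa": -1, "atp": -1, "nadph": -1, "h2o": -1,
           "thr__L": 1, "adp": 1, "pi": 1, "nadp": 1},
          gpr="thrB_syn", subsystem="amino_acid", balance=True)
    b.add("LYSSYN", "lysine synthesis via diaminopimelate (lumped)",
          {"aspsa": -1, "pyr": -1, "glu__L": -1, "nadph": -1,
           "lys__L": 1, "akg": 1, "co2": 1, "nadp": 1},
          gpr="dapA_syn", subsystem="amino_acid", balance=True)


def _add_optional_aa_synthesis(b: _Builder, which) -> None:
    """Biosynthesis lumps for the auxotrophy-candidate amino acids."""
    if "met__L" in which:
        b.add("METSYN", "methionine synthesis (lumped homocysteine + C1 route)",
              {"aspsa": -1, "for": -1, "h2s": -1, "nadph": -3,
               "met__L": 1, "nadp": 3},
              gpr="metB_syn", subsystem="amino_acid", balance=True)
    if "leu__L" in which:
        b.add("LEUSYN", "leucine synthesis (lumped)",
              {"pyr": -2, "accoa": -1, "glu__L": -1, "nadph": -1, "nad": -1,
               "leu__L": 1, "co2": 2, "coa": 1, "akg": 1, "nadp": 1, "nadh": 1},
              gpr="leuA_syn", subsystem="amino_acid", balance=True)
    if "arg__L" in which:
        b.add("ARGSYN", "arginine synthesis (lumped)",
              {"glu__L": -2, "co2": -1, "nh4": -1, "asp__L": -1, "atp": -4,
               "nadph": -1, "arg__L": 1, "akg": 1, "fum": 1, "adp": 4,
               "pi": 4, "nadp": 1},
              gpr="argG_syn", subsystem="amino_acid", balance=True)
    if "ile__L" in which:
        b.add("ILESYN", "isoleucine synthesis (lumped)",
              {"thr__L": -1, "pyr": -1, "glu__L": -1, "nadph": -1,
               "ile__L": 1, "nh4": 1, "co2": 1, "akg": 1, "nadp": 1},
              gpr="ilvA_syn", subsystem="amino_acid", balance=True)
    if "val__L" in which:
        b.add("VALSYN", "valine synthesis (lumped)",
              {"pyr": -2, "glu__L": -1, "nadph": -1,
               "val__L": 1, "co2": 1, "akg": 1, "nadp": 1},
              gpr="ilvD_syn", subsystem="amino_acid", balance=True)


def _biomass_composition(amino_acids: dict, cell_wall_fraction: float = 0.20):
    total = sum(amino_acids.values())
    comp = MacromoleculeComposition(
        protein={aa: f / total for aa, f in amino_acids.items()},
        rna={"AMP": 0.5, "UMP": 0.5},
        mass_fractions={"protein": 0.50, "rna": 0.15, "cell_wall": cell_wall_fraction},
        extra={"cell_wall": {"udpg_c": 0.5, "uacgam_c": 0.5}},
    )
    weights = {
        "udpg_c": formula_weight(_METS["udpg"][1]),
        "uacgam_c": formula_weight(_METS["uacgam"][1]),
    }
    return comp, weights


# -- native model --------------------------------------------------------------

#: one-letter codes of the native protein composition (relative molar weights)
_NATIVE_PROTEIN = {
    "E": 0.10, "Q": 0.05, "A": 0.12, "D": 0.08, "N": 0.05, "S": 0.07,
    "T": 0.06, "K": 0.08, "M": 0.03, "L": 0.10, "R": 0.06, "I": 0.09,
    "V": 0.11,
}
_RECOMBINANT_PROTEIN = {
    "E": 0.12, "Q": 0.06, "A": 0.13, "D": 0.10, "S": 0.08, "T": 0.08,
    "K": 0.10, "M": 0.04, "L": 0.12, "R": 0.08, "G": 0.09,
}

_AA_BASE = {
    "E": "glu__L", "Q": "gln__L", "A": "ala__L", "D": "asp__L",
    "N": "asn__L", "S": "ser__L", "T": "thr__L", "K": "lys__L",
    "M": "met__L", "L": "leu__L", "R": "arg__L", "I": "ile__L",
    "V": "val__L", "G": "gly",
}


def make_native_model(params: SyntheticModelParams | None = None) -> MetabolicModel:
    """The native HA producer: fermentative, fastidious, HA operon on board.

    Ships with its default chemically defined medium applied (anaerobic,
    glucose uptake 18.56 mmol.gDCW^-1.h^-1, all amino acids and nucleobases
    supplied).
    """
    p = params or SyntheticModelParams()
    b = _Builder("syn_native")
    auxotrophies = set(AUXOTROPHY_CANDIDATES[: p.n_auxotrophies])

    _add_glycolysis(b)
    _add_nonox_ppp(b)
    _add_ha_branch(b)
    _add_nucleotides(b, salvage=True)
    _add_core_amino_acids(b)
    synthesizable = set(AUXOTROPHY_CANDIDATES) - auxotrophies
    _add_optional_aa_synthesis(b, synthesizable)
    if "met__L" in synthesizable:  # methionine synthesis needs a sulfide source
        b.exchange("h2s")
    if "arg__L" in synthesizable:  # no TCA sink for the fumarate by-product
        b.exchange("fum", transport="export")

    # NADPH source of streptococci: non-phosphorylating NADP-GAPDH
    b.add("GAPN", "NADP-dependent glyceraldehyde-3-phosphate dehydrogenase",
          {"g3p": -1, "nadp": -1, "h2o": -1, "3pg": 1, "nadph": 1, "h": 2},
          gpr="gapN_syn", subsystem="glycolysis")
    # fermentation
    b.add("LDH_D", "D-lactate dehydrogenase",
          {"pyr": -1, "nadh": -1, "h": -1, "lac__D": 1, "nad": 1},
          gpr="ldh_syn", lb=-1000.0, subsystem="fermentation")
    b.add("PFL", "pyruvate formate-lyase",
          {"pyr": -1, "coa": -1, "accoa": 1, "for": 1},
          gpr="pfl_syn", subsystem="fermentation")
    b.add("NOX", "NADH oxidase (water-forming)",
          {"nadh": -2, "o2": -1, "h": -2, "nad": 2, "h2o": 2},
          gpr="nox_syn", subsystem="fermentation")
    # mixed-acid overflow; the acetate kinase capacity cap keeps the wild
    # type homolactic at high glycolytic flux
    b.add("PTAr", "phosphotransacetylase",
          {"accoa": -1, "pi": -1, "actp": 1, "coa": 1},
          gpr="pta_syn", lb=-1000.0, subsystem="fermentation")
    b.add("ACKr", "acetate kinase",
          {"actp": -1, "adp": -1, "ac": 1, "atp": 1},
          gpr="ackA_syn", lb=0.0, ub=_ACETATE_KINASE_CAP,
          subsystem="fermentation")
    # anaplerosis and truncated oxidative TCA branch to 2-oxoglutarate
    b.add("PPC", "phosphoenolpyruvate carboxylase",
          {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1, "h": 1},
          gpr="ppc_syn", subsystem="tca")
    b.add("CS", "citrate synthase",
          {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1, "h": 1},
          gpr="gltA_syn", subsystem="tca")
    b.add("ACONT", "aconitase", {"cit": -1, "icit": 1},
          gpr="acn_syn", lb=-1000.0, subsystem="tca")
    b.add("ICDHx", "isocitrate dehydrogenase (NAD)",
          {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1},
          gpr="icd_syn", subsystem="tca")
    # carbon-source funnels
    b.add("FRUK", "fructokinase",
          {"fru": -1, "atp": -1, "f6p": 1, "adp": 1, "h": 1},
          gpr="fruK_syn", subsystem="sugar")
    b.add("SUCR_HYD", "sucrose hydrolase (invertase)",
          {"sucr": -1, "h2o": -1, "glc__D": 1, "fru": 1},
          gpr="sacA_syn", subsystem="sugar")
    b.add("MALT_HYD", "maltose hydrolase",
          {"malt": -1, "h2o": -1, "glc__D": 2},
          gpr="malL_syn", subsystem="sugar")
    b.add("LCTS_HYD", "lactose hydrolase (beta-galactosidase)",
          {"lcts": -1, "h2o": -1, "glc__D": 1, "gal": 1},
          gpr="lacZ_syn", subsystem="sugar")
    b.add("GALK_LUMP", "galactose entry via Leloir route (lumped)",
          {"gal": -1, "atp": -1, "g1p": 1, "adp": 1, "h": 1},
          gpr="galK_syn", subsystem="sugar")

    # exchanges and transports
    b.exchange("glc__D", gpr="glcU_syn")
    for sugar in ("fru", "sucr", "malt", "lcts"):
        b.exchange(sugar)
    amino_acids = sorted({_AA_BASE[a] for a in _NATIVE_PROTEIN})
    for aa in amino_acids:
        gpr = "metN_syn and metQ_syn" if aa == "met__L" else ""
        b.exchange(aa, gpr=gpr)
    for base in ("ade", "ura"):
        b.exchange(base)
    for base in ("nh4", "pi", "h2o", "h", "co2", "o2"):
        b.exchange(base, transport="free")
    for base in ("lac__D", "for", "ac"):
        b.exchange(base, transport="export")

    # maintenance and biomass
    maint = MaintenanceParameters(gam=p.gam, ngam=p.ngam)
    b.reactions.append(ngam_reaction(maint))
    comp, weights = _biomass_composition(_NATIVE_PROTEIN)
    b.reactions.append(assemble_biomass(comp, maint, extra_monomer_weights=weights))

    model = b.build(objective="BIOMASS", genome_gene_count=2049)
    uptake = p.glucose_uptake if p.glucose_uptake is not None else 18.56
    return apply_medium(model, native_cdm_medium(model, aerobic=False, glucose_uptake=uptake))


def native_cdm_medium(
    model: MetabolicModel,
    aerobic: bool = False,
    glucose_uptake: float = 18.56,
    amino_acid_bound: float = 10.0,
    nucleobase_bound: float = 5.0,
    oxygen_bound: float = 20.0,
) -> Medium:
    """Chemically defined medium for the native producer.

    Supplies glucose at the chemostat rate, every amino acid of the protein
    composition, the salvage nucleobases and free inorganics; oxygen is
    closed unless ``aerobic``.
    """
    bounds = {"EX_glc__D_e": (-glucose_uptake, 1000.0)}
    for aa in sorted({_AA_BASE[a] for a in _NATIVE_PROTEIN}):
        bounds[f"EX_{aa}_e"] = (-amino_acid_bound, 1000.0)
    for base in ("ade", "ura"):
        bounds[f"EX_{base}_e"] = (-nucleobase_bound, 1000.0)
    for base in ("nh4", "pi", "h2o", "h", "co2"):
        bounds[f"EX_{base}_e"] = (-1000.0, 1000.0)
    bounds["EX_o2_e"] = (-oxygen_bound, 1000.0) if aerobic else (0.0, 1000.0)
    return Medium(bounds, name="CDM (aerobic)" if aerobic else "CDM (anaerobic)")


# -- recombinant model ---------------------------------------------------------


def make_recombinant_model(params: SyntheticModelParams | None = None) -> MetabolicModel:
    """The recombinant HA host: prototrophic aerobe with oxidative PPP,
    full TCA cycle and lumped oxidative phosphorylation, carrying the HA
    operon heterologously.  Ships with its minimal medium applied (aerobic,
    glucose uptake 4.67 mmol.gDCW^-1.h^-1).
    """
    p = params or SyntheticModelParams(
        include_oxidative_ppp=True, include_full_tca=True, n_auxotrophies=0
    )
    b = _Builder("syn_recombinant")

    _add_glycolysis(b)
    _add_nonox_ppp(b)
    _add_ha_branch(b)
    _add_nucleotides(b, salvage=False)
    _add_core_amino_acids(b)
    _add_optional_aa_synthesis(b, {"met__L", "leu__L", "arg__L"})

    if p.include_oxidative_ppp:
        b.add("ZWF_LUMP", "oxidative pentose-phosphate branch (G6P dehydrogenase, lumped)",
              {"g6p": -1, "nadp": -2, "h2o": -1, "ru5p__D": 1, "co2": 1, "nadph": 2},
              gpr="zwf_syn", subsystem="ppp", balance=True)
    # C1 and purine de novo
    b.add("C1LUMP", "serine-derived C1 unit, oxidized to formate (lumped)",
          {"ser__L": -1, "nad": -1, "gly": 1, "for": 1, "nadh": 1},
          gpr="glyA_syn", subsystem="amino_acid", balance=True)
    b.add("PURSYN", "purine de novo synthesis to AMP (lumped)",
          {"prpp": -1, "gly": -1, "gln__L": -2, "asp__L": -2, "co2": -1,
           "for": -2, "atp": -5, "amp": 1, "glu__L": 2, "fum": 2,
           "adp": 5, "pi": 5, "ppi": 1},
          gpr="purF_syn", subsystem="nucleotide", balance=True)
    # fermentative overflow (lactate is the recombinant host's main by-product)
    b.add("LDH_D", "D-lactate dehydrogenase",
          {"pyr": -1, "nadh": -1, "h": -1, "lac__D": 1, "nad": 1},
          gpr="ldh_syn", lb=-1000.0, subsystem="fermentation")
    # full TCA cycle
    b.add("PDH", "pyruvate dehydrogenase complex",
          {"pyr": -1, "coa": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1},
          gpr="aceE_syn and aceF_syn", subsystem="tca")
    b.add("PPC", "phosphoenolpyruvate carboxylase",
          {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1, "h": 1},
          gpr="ppc_syn", subsystem="tca")
    b.add("CS", "citrate synthase",
          {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1, "h": 1},
          gpr="gltA_syn", subsystem="tca")
    b.add("ACONT", "aconitase", {"cit": -1, "icit": 1},
          gpr="acn_syn", lb=-1000.0, subsystem="tca")
    b.add("ICDHx", "isocitrate dehydrogenase (NAD)",
          {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1},
          gpr="icd_syn", subsystem="tca")
    b.add("ICDHyr", "isocitrate dehydrogenase (NADP)",
          {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1},
          gpr="icd2_syn", subsystem="tca")
    b.add("AKGDH", "2-oxoglutarate dehydrogenase complex",
          {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1},
          gpr="sucA_syn and sucB_syn and lpd_syn", subsystem="tca")
    b.add("SUCOAS", "succinyl-CoA synthetase",
          {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "atp": 1, "coa": 1},
          gpr="sucCD_syn", lb=-1000.0, subsystem="tca")
    b.add("SUCFUM", "succinate oxidation to fumarate (lumped, P/O 1)",
          {"succ": -2, "o2": -1, "adp": -2, "pi": -2, "fum": 2, "atp": 2},
          gpr="sdhA_syn", subsystem="tca", balance=True)
    b.add("FUM", "fumarase",
          {"fum": -1, "h2o": -1, "mal__L": 1},
          gpr="fum_syn", lb=-1000.0, subsystem="tca")
    b.add("MDH", "malate dehydrogenase",
          {"mal__L": -1, "nad": -1, "oaa": 1, "nadh": 1, "h": 1},
          gpr="mdh_syn", lb=-1000.0, subsystem="tca")
    b.add("OXPHOS", "NADH oxidation with ATP synthesis (lumped, P/O 2)",
          {"nadh": -2, "o2": -1, "adp": -4, "pi": -4, "nad": 2, "atp": 4},
          gpr="nadhd_syn", subsystem="etc", balance=True)

    # exchanges
    b.exchange("glc__D", gpr="glcU_syn")
    for base in ("nh4", "pi", "h2o", "h", "co2", "o2"):
        b.exchange(base, transport="free")
    b.exchange("h2s")
    for base in ("lac__D", "for", "gly"):
        b.exchange(base, transport="export")

    maint = MaintenanceParameters(gam=p.gam, ngam=p.ngam)
    b.reactions.append(ngam_reaction(maint))
    comp, weights = _biomass_composition(_RECOMBINANT_PROTEIN)
    b.reactions.append(assemble_biomass(comp, maint, extra_monomer_weights=weights))

    model = b.build(objective="BIOMASS", genome_gene_count=3057)
    uptake = p.glucose_uptake if p.glucose_uptake is not None else 4.67
    return apply_medium(model, recombinant_minimal_medium(model, glucose_uptake=uptake))


def recombinant_minimal_medium(
    model: MetabolicModel,
    glucose_uptake: float = 4.67,
    oxygen_bound: float = 20.0,
    aerobic: bool = True,
) -> Medium:
    """Minimal salts medium for the prototrophic recombinant host."""
    bounds = {
        "EX_glc__D_e": (-glucose_uptake, 1000.0),
        "EX_h2s_e": (-10.0, 1000.0),
        "EX_o2_e": (-oxygen_bound, 1000.0) if aerobic else (0.0, 1000.0),
    }
    for base in ("nh4", "pi", "h2o", "h", "co2"):
        bounds[f"EX_{base}_e"] = (-1000.0, 1000.0)
    return Medium(bounds, name="minimal medium")


# -- validation fixture --------------------------------------------------------

# Published growth phenotypes of the native producer under single amino-acid
# omission from a chemically defined medium, paired with a curated model's
# predictions (G = growth, NG = no growth).
_AA_OMISSION_LABELS = [
    ("CDM1", "G", "G"),
    ("CDM1- Asp", "G", "G"),
    ("CDM1- Asn", "G", "G"),
    ("CDM1- Lys", "NG", "G"),
    ("CDM1- Met", "NG", "NG"),
    ("CDM1- Thr", "G", "G"),
    ("CDM1- Ile", "NG", "NG"),
    ("CDM1- Ala", "G", "G"),
    ("CDM1- Val", "NG", "NG"),
    ("CDM1- Leu", "NG", "NG"),
    ("CDM1- Tyr", "NG", "NG"),
    ("CDM1- Phe", "NG", "NG"),
    ("CDM1- Trp", "G", "G"),
    ("CDM1- Ser", "G", "G"),
    ("CDM1- Gly", "G", "G"),
    ("CDM1- Cys", "NG", "NG"),
    ("CDM1- Glu", "G", "G"),
    ("CDM1- Pro", "G", "G"),
    ("CDM1- Orn", "G", "G"),
    ("CDM1- Arg", "NG", "NG"),
    ("CDM1- His", "NG", "NG"),
    ("CDM1- Gln", "NG", "G"),
]

# Published carbon-source utilization phenotypes with model predictions.
_CARBON_SOURCE_LABELS = [
    ("No sugar", "NG", "NG"),
    ("Glucose", "G", "G"),
    ("Sucrose", "G", "G"),
    ("Fructose", "G", "G"),
    ("Maltose", "G", "G"),
    ("Lactose", "G", "G"),
]


def make_validation_fixture() -> tuple:
    """Reference screen-label fixtures for the confusion-metric machinery.

    Returns (amino-acid omission screen, carbon-source screen) with the
    experimental and predicted growth calls of the published validation
    experiments; the first tallies to TP=11, FP=2, TN=9, FN=0 and the second
    to TP=5, TN=1.
    """
    aa = ScreenResult(
        [ScreenRow(c, predicted=p, experimental=e) for c, e, p in _AA_OMISSION_LABELS],
        name="amino-acid omission",
    )
    carbon = ScreenResult(
        [ScreenRow(c, predicted=p, experimental=e) for c, e, p in _CARBON_SOURCE_LABELS],
        name="carbon sources",
    )
    return aa, carbon
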