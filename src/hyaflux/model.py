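"""Core domain types for constraint-based metabolic models.

Conventions follow standard COBRA practice: the stoichiometric matrix ``S``
has one row per metabolite and one column per reaction; steady state is
``S v = 0`` with ``lb <= v <= ub``; exchange reactions import at negative
flux and secrete at positive flux; reversible internal reactions default to
bounds (-1000, 1000) and irreversible ones to (0, 1000), all in
mmol.gDCW^-1.h^-1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .gpr import GprRule, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Medium",
    "BalanceReport",
    "ModelValidationError",
    "build_stoichiometric_matrix",
    "check_balance",
    "apply_medium",
    "parse_formula",
    "formula_weight",
    "DEFAULT_BOUND",
]

DEFAULT_BOUND = 1000.0

INTRACELLULAR = "c"
EXTRACELLULAR = "e"
COMPARTMENTS = (INTRACELLULAR, EXTRACELLULAR)

REACTION_KINDS = ("internal", "exchange", "transport", "pseudo")


class ModelValidationError(ValueError):
    """A model or one of its components violates a structural invariant."""


# -- chemical formulas -------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: Standard atomic weights (g/mol) for the elements used by the toy models.
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Mg": 24.305,
    "Fe": 55.845,
    "Cl": 35.45,
}


def parse_formula(formula: str) -> dict:
    """Parse a Hill-style formula string (e.g. ``"C6H12O6"``) to element counts."""
    counts: dict = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        element, n = m.group(1), int(m.group(2) or 1)
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a formula string."""
    return sum(ATOMIC_MASS[el] * n for el, n in parse_formula(formula).items())


# -- domain types ------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` may be None for pool species (e.g. a polymer unit of unknown
    composition); such metabolites make reactions "unbalanceable" rather than
    unbalanced.
    """

    id: str
    name: str = ""
    formula: str | None = None
    charge: int = 0
    compartment: str = INTRACELLULAR

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id}: unknown compartment {self.compartment!r}"
            )

    @property
    def elements(self) -> dict | None:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``kind`` is one of internal / exchange / transport / pseudo;
    exchange and pseudo reactions are exempt from elemental balance checks.
    """

    id: str
    stoichiometry: dict
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GprRule = field(default_factory=GprRule)
    kind: str = "internal"
    name: str = ""
    subsystem: str = ""

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = parse_gpr(self.gpr)
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id}: unknown kind {self.kind!r}")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))

    def equation(self, arrow_for=None) -> str:
        """Human-readable equation string, e.g. ``"glc_c + atp_c --> g6p_c + adp_c"``."""

        def side(items):
            parts = []
            for met, coef in items:
                c = abs(coef)
                # repr round-trips floats exactly through the TSV dialect
                parts.append(met if c == 1 else f"{c!r} {met}")
            return " + ".join(parts)

        subs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        prods = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<=>" if self.reversible else "-->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class Medium:
    """Exchange-reaction bounds defining a growth medium.

    Maps exchange reaction id to a ``(lower, upper)`` flux pair; a negative
    lower bound is an uptake allowance.
    """

    exchange_bounds: dict = field(default_factory=dict)
    name: str = ""

    def items(self):
        return self.exchange_bounds.items()


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites, reactions, genes and an objective."""

    id: str = "model"
    metabolites: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    objective_reaction: str = ""
    genome_gene_count: int | None = None

    # -- lookups -------------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"no metabolite {met_id!r} in model {self.id}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id}")

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    def exchange_reactions(self) -> list:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction=self.objective_reaction,
            genome_gene_count=self.genome_gene_count,
        )

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raises ModelValidationError on failure."""
        met_ids = self.metabolite_ids
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = self.reaction_ids
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_index = {m.id: m for m in self.metabolites}
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
            missing = rxn.gpr.genes - gene_set
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id}: GPR genes not in model gene list: {sorted(missing)}"
                )
            if rxn.kind == "exchange":
                ext = [m for m in rxn.stoichiometry if met_index[m].compartment == EXTRACELLULAR]
                if len(rxn.stoichiometry) != 1 or len(ext) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {rxn.id} must touch exactly one "
                        f"extracellular metabolite"
                    )
        if self.objective_reaction and self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )


# -- operations --------------------------------------------------------------


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions).

    Row/column order follows ``model.metabolites`` / ``model.reactions``.
    """
    model.validate()
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            S[met_pos[met_id], j] = coef
    return S


@dataclass
class BalanceReport:
    """Per-element and charge residuals of one reaction.

    ``status``: "balanced", "unbalanced", "exempt" (exchange/pseudo) or
    "unbalanceable" (a participant lacks a formula).
    """

    reaction_id: str
    status: str
    element_residuals: dict = field(default_factory=dict)
    charge_residual: float = 0.0

    @property
    def is_balanced(self) -> bool:
        return self.status == "balanced"


def check_balance(
    reaction: Reaction,
    metabolite_table,
    tolerance: float = 1e-9,
) -> BalanceReport:
    """Elemental and charge balance of one reaction.

    ``metabolite_table`` is a mapping of metabolite id to Metabolite (or a
    MetabolicModel).  Exchange and pseudo reactions are flagged exempt: they
    intentionally create or destroy mass.
    """
    if isinstance(metabolite_table, MetabolicModel):
        metabolite_table = {m.id: m for m in metabolite_table.metabolites}
    if reaction.kind in ("exchange", "pseudo"):
        return BalanceReport(reaction.id, "exempt")

    residuals: dict = {}
    charge = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        met = metabolite_table[met_id]
        if met.formula is None:
            return BalanceReport(reaction.id, "unbalanceable")
        for element, n in met.elements.items():
            residuals[element] = residuals.get(element, 0.0) + coef * n
        charge += coef * met.charge
    residuals = {el: r for el, r in residuals.items() if abs(r) > tolerance}
    status = "balanced" if not residuals and abs(charge) <= tolerance else "unbalanced"
    return BalanceReport(reaction.id, status, residuals, charge)


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Return a copy of ``model`` with exchange bounds set from ``medium``.

    Exchanges listed in the medium get exactly the listed (lower, upper)
    bounds; every *unlisted* exchange has its uptake closed (lower bound
    raised to 0) while its secretion bound is left untouched.  Internal
    reaction bounds are never altered.
    """
    exchange_ids = {r.id for r in model.exchange_reactions()}
    unknown = set(medium.exchange_bounds) - exchange_ids
    if unknown:
        raise KeyError(
            f"medium references non-exchange or missing reactions: {sorted(unknown)}"
        )
    out = model.copy()
    for rxn in out.reactions:
        if rxn.kind != "exchange":
            continue
        if rxn.id in medium.exchange_bounds:
            lo, hi = medium.exchange_bounds[rxn.id]
            if lo > hi:
                raise ModelValidationError(
                    f"medium bound for {rxn.id}: lower {lo} exceeds upper {hi}"
                )
            rxn.lower_bound, rxn.upper_bound = float(lo), float(hi)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return out
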