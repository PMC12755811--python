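"""Gene-deletion screens and genetic-interaction classification.

A gene knockout disables every reaction whose GPR rule evaluates false with
the deleted genes absent (bounds set to 0); reactions with an empty GPR are
untouched.  The relative growth rate Rgr = mu_mutant / mu_wildtype drives the
classification:

* single deletions — lethal (Rgr ~ 0), sick (Rgr < 1), neutral;
* double deletions — synthetic lethal (double lethal although neither single
  is), synthetic sick (double growth strictly below both singles), or no
  interaction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fba import fba
from .model import MetabolicModel
from .moma import moma, reference_state

__all__ = [
    "DeletionResult",
    "InteractionSummary",
    "knockout",
    "single_gene_deletion",
    "double_gene_deletion",
    "summarize_interactions",
    "ZERO_GROWTH_TOL",
    "SICK_TOL",
]

#: Rgr below this counts as zero growth (lethal).
ZERO_GROWTH_TOL = 1e-6
#: Rgr below 1 - SICK_TOL counts as a real growth defect (sick).
SICK_TOL = 1e-3


def knockout(model: MetabolicModel, genes) -> MetabolicModel:
    """Copy of ``model`` with all reactions requiring ``genes`` disabled.

    Disabling sets both bounds to 0; the operation is idempotent.
    """
    genes = set([genes] if isinstance(genes, str) else genes)
    unknown = genes - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene id(s): {sorted(unknown)}")
    out = model.copy()
    for rxn in out.reactions:
        if not rxn.gpr.is_empty and not rxn.gpr.evaluate(genes):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


@dataclass
class DeletionResult:
    """Outcome of deleting one gene or one gene pair."""

    genes: frozenset
    growth: float
    rgr: float  # mutant growth / wild-type growth
    method: str  # fba | moma
    klass: str  # lethal | sick | neutral | synthetic_lethal | synthetic_sick | no_interaction

    @property
    def lethal(self) -> bool:
        return self.klass in ("lethal", "synthetic_lethal")


def _classify_single(rgr: float) -> str:
    if rgr <= ZERO_GROWTH_TOL:
        return "lethal"
    if rgr < 1.0 - SICK_TOL:
        return "sick"
    return "neutral"


def _mutant_growth(model, genes, method, reference):
    mut = knockout(model, genes)
    if method == "fba":
        sol = fba(mut)
        return max(sol.objective_value, 0.0) if sol.optimal else 0.0
    sol = moma(mut, reference)
    return max(sol.fluxes.objective_value, 0.0) if sol.optimal else 0.0


def _wild_type(model, method):
    if method not in ("fba", "moma"):
        raise ValueError(f"unknown deletion method {method!r}")
    wt = fba(model)
    if not wt.optimal or wt.objective_value <= ZERO_GROWTH_TOL:
        raise RuntimeError("wild-type model does not grow; screen is undefined")
    reference = reference_state(model) if method == "moma" else None
    return wt.objective_value, reference


def single_gene_deletion(
    model: MetabolicModel, method: str = "fba", genes=None
) -> list:
    """Screen every gene (or a subset) for its single-deletion growth effect."""
    mu_wt, reference = _wild_type(model, method)
    results = []
    for gene in genes if genes is not None else model.genes:
        growth = _mutant_growth(model, {gene}, method, reference)
        rgr = growth / mu_wt
        results.append(
            DeletionResult(frozenset({gene}), growth, rgr, method, _classify_single(rgr))
        )
    return results


def double_gene_deletion(
    model: MetabolicModel,
    method: str = "fba",
    singles: list | None = None,
    genes=None,
) -> list:
    """Screen all gene pairs and classify genetic interactions.

    A pair interacts when the double-mutant growth falls strictly below both
    single-mutant growths; interaction with zero double growth (and both
    singles viable) is synthetic lethal, any other interacting pair with
    Rgr < 1 is synthetic sick.
    """
    gene_list = list(genes) if genes is not None else list(model.genes)
    if singles is None:
        singles = single_gene_deletion(model, method, genes=gene_list)
    single_rgr = {next(iter(r.genes)): r.rgr for r in singles}
    mu_wt, reference = _wild_type(model, method)
    results = []
    for g1, g2 in itertools.combinations(gene_list, 2):
        growth = _mutant_growth(model, {g1, g2}, method, reference)
        rgr = growth / mu_wt
        r1, r2 = single_rgr[g1], single_rgr[g2]
        min_single = min(r1, r2)
        interacts = rgr < min_single - SICK_TOL
        if interacts and rgr <= ZERO_GROWTH_TOL and min(r1, r2) > ZERO_GROWTH_TOL:
            klass = "synthetic_lethal"
        elif interacts and rgr < 1.0 - SICK_TOL:
            klass = "synthetic_sick"
        else:
            klass = "no_interaction"
        results.append(DeletionResult(frozenset({g1, g2}), growth, rgr, method, klass))
    return results


@dataclass
class InteractionSummary:
    """Percent-of-genes summary of a single + double deletion screen.

    Single-deletion classes use the total gene count as denominator; the
    interaction-degree classes count genes with at least 1 (or at least 5)
    synthetic-lethal/sick partners, again as a percentage of all genes.
    """

    pct_lethal: float
    pct_sick: float
    pct_synthetic_lethal_1: float
    pct_synthetic_sick_1: float
    pct_synthetic_lethal_ge5: float
    pct_synthetic_sick_ge5: float
    n_genes: int = 0
    degrees: dict = field(default_factory=dict, repr=False)


def summarize_interactions(
    singles: list, doubles: list, n_genes: int | None = None
) -> InteractionSummary:
    """Tabulate lethal/sick percentages and synthetic-interaction degrees."""
    genes = sorted({g for r in singles for g in r.genes})
    n = n_genes if n_genes is not None else len(genes)
    if n == 0:
        raise ValueError("no genes in screen")
    pct = lambda k: 100.0 * k / n
    n_lethal = sum(r.klass == "lethal" for r in singles)
    n_sick = sum(r.klass == "sick" for r in singles)

    deg_lethal: dict = {g: 0 for g in genes}
    deg_sick: dict = {g: 0 for g in genes}
    for r in doubles:
        if r.klass not in ("synthetic_lethal", "synthetic_sick"):
            continue
        target = deg_lethal if r.klass == "synthetic_lethal" else deg_sick
        for g in r.genes:
            target[g] = target.get(g, 0) + 1

    count_ge = lambda deg, k: sum(1 for d in deg.values() if d >= k)
    return InteractionSummary(
        pct_lethal=pct(n_lethal),
        pct_sick=pct(n_sick),
        pct_synthetic_lethal_1=pct(count_ge(deg_lethal, 1)),
        pct_synthetic_sick_1=pct(count_ge(deg_sick, 1)),
        pct_synthetic_lethal_ge5=pct(count_ge(deg_lethal, 5)),
        pct_synthetic_sick_ge5=pct(count_ge(deg_sick, 5)),
        n_genes=n,
        degrees={"synthetic_lethal": deg_lethal, "synthetic_sick": deg_sick},
    )
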