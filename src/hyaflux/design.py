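"""Strain-design procedures for product (hyaluronic acid) overproduction.

Two complementary searches are provided:

* :func:`iterative_knockout_search` — iterative single-gene deletion: each
  round deletes one more gene in the background of a surviving mutant and
  evaluates the product rate by MOMA (or FBA) against the *wild-type*
  reference; deletions are kept when the product rate improves, and a
  round-one candidate is not expanded further if it costs more than a
  configurable fraction (default 40%) of the growth rate.

* :func:`sample_alternate_optima` / :func:`regulation_targets` — alternate
  optimal flux distributions are sampled on the optimal face (product pinned
  to its extreme at >= 95% of optimal growth, random secondary objectives),
  and reactions whose flux ranges under maximized vs minimized product are
  strictly separated are nominated as up- or down-regulation targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deletions import ZERO_GROWTH_TOL, knockout
from .fba import FEASIBILITY_TOL, FluxDistribution, fba, fix_growth_fraction, solve_lp
from .model import MetabolicModel
from .moma import moma, reference_state

__all__ = [
    "SearchConfig",
    "MutantStrategy",
    "AltOptimaConfig",
    "RegulationTarget",
    "iterative_knockout_search",
    "sample_alternate_optima",
    "regulation_targets",
]


@dataclass
class SearchConfig:
    """Parameters of the iterative knockout search."""

    product_reaction: str
    max_depth: int = 3
    growth_drop_cutoff: float = 0.40  # round-one mutants losing more growth are not expanded
    improvement_threshold: float = 0.01  # relative product-rate gain required to keep a deletion
    method: str = "moma"  # moma | fba
    min_absolute_gain: float = 1e-4  # guards the relative test when the parent rate is ~0

    def __post_init__(self):
        if not 0 < self.growth_drop_cutoff < 1:
            raise ValueError("growth_drop_cutoff must be in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.method not in ("moma", "fba"):
            raise ValueError(f"unknown search method {self.method!r}")


@dataclass
class MutantStrategy:
    """An ordered knockout set with its predicted phenotype."""

    knockouts: tuple
    growth: float
    growth_ratio_to_wild: float
    product_rate: float
    round: int

    def __post_init__(self):
        assert self.round == len(self.knockouts)


def _evaluate(model, genes, config, reference):
    """(growth, product rate) of a knockout strain, by MOMA or FBA."""
    mut = knockout(model, set(genes))
    if config.method == "moma":
        sol = moma(mut, reference)
        if not sol.optimal:
            return 0.0, 0.0
        fluxes = sol.fluxes
    else:
        fluxes = fba(mut)
        if not fluxes.optimal:
            return 0.0, 0.0
    growth = max(fluxes.objective_value, 0.0)
    product = fluxes.get(config.product_reaction, 0.0)
    return growth, product


def iterative_knockout_search(
    model: MetabolicModel, config: SearchConfig
) -> list:
    """Breadth-first iterative single-gene deletion for product overproduction.

    Round r evaluates every additional single deletion in each surviving
    (r-1)-mutant background; a deletion survives when the product rate
    improves by at least ``improvement_threshold`` relative to its parent.
    The growth-drop cutoff applies to round-one candidates only.  The MOMA
    reference is always the wild-type state.  Results are deterministic for a
    fixed model and config, and sorted by product rate (descending).
    """
    model.reaction(config.product_reaction)
    reference = reference_state(model)
    mu_wt = reference.objective_value
    if mu_wt <= ZERO_GROWTH_TOL:
        raise RuntimeError("wild type does not grow; search is undefined")
    p_wt = reference.get(config.product_reaction, 0.0)

    def improved(p_new: float, p_parent: float) -> bool:
        if p_new - p_parent < config.min_absolute_gain:
            return False
        base = max(p_parent, config.min_absolute_gain)
        return (p_new - p_parent) / base >= config.improvement_threshold

    strategies: list = []
    # frontier: (knockout tuple, parent product rate)
    frontier = [((), p_wt)]
    for depth in range(1, config.max_depth + 1):
        next_frontier = []
        for parent_kos, p_parent in frontier:
            used = set(parent_kos)
            for gene in model.genes:
                if gene in used:
                    continue
                kos = parent_kos + (gene,)
                growth, product = _evaluate(model, kos, config, reference)
                if growth <= ZERO_GROWTH_TOL or not improved(product, p_parent):
                    continue
                strategy = MutantStrategy(
                    knockouts=kos,
                    growth=growth,
                    growth_ratio_to_wild=growth / mu_wt,
                    product_rate=product,
                    round=depth,
                )
                strategies.append(strategy)
                if depth == 1 and strategy.growth_ratio_to_wild < 1 - config.growth_drop_cutoff:
                    continue  # too costly in round one: reported, not expanded
                next_frontier.append((kos, product))
        frontier = next_frontier
        if not frontier:
            break
    strategies.sort(key=lambda s: (-s.product_rate, s.knockouts))
    return strategies


@dataclass
class AltOptimaConfig:
    """Parameters of alternate-optima sampling on the optimal face."""

    n_samples: int = 5000
    growth_fraction: float = 0.95
    seed: int = 0
    objective_tolerance: float = 1e-6

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 < self.growth_fraction <= 1:
            raise ValueError("growth_fraction must be in (0, 1]")


def sample_alternate_optima(
    model: MetabolicModel,
    objective_reaction: str,
    config: AltOptimaConfig,
    direction: str = "maximize",
) -> list:
    """Sample flux distributions on the optimal face of a product objective.

    Growth is constrained to >= growth_fraction x mu*, the product flux is
    pinned to its extreme value (within ``objective_tolerance``), and each
    sample optimizes a random secondary objective drawn from a seeded RNG —
    yielding many distinct alternate optima with identical product rate.
    """
    constrained = fix_growth_fraction(model, config.growth_fraction)
    extreme = fba(constrained, objective_reaction, direction)
    if not extreme.optimal:
        raise RuntimeError(f"growth-constrained model infeasible ({extreme.status})")
    p_star = extreme.objective_value
    tol = config.objective_tolerance
    prod = constrained.reaction(objective_reaction)
    lo = max(prod.lower_bound, p_star - tol) if direction == "maximize" else prod.lower_bound
    hi = prod.upper_bound if direction == "maximize" else min(prod.upper_bound, p_star + tol)
    if direction == "maximize":
        hi = min(hi, p_star + tol)
    else:
        lo = max(lo, p_star - tol)
    face = constrained.copy()
    rxn = face.reaction(objective_reaction)
    rxn.lower_bound, rxn.upper_bound = lo, hi

    rng = np.random.default_rng(config.seed)
    rxn_ids = face.reaction_ids
    samples = []
    for _ in range(config.n_samples):
        weights = rng.standard_normal(len(rxn_ids))
        sol = solve_lp(face, dict(zip(rxn_ids, weights)), "maximize")
        if not sol.optimal:  # numerically pinched face; keep going
            continue
        sol.objective_reaction = objective_reaction
        sol.objective_value = sol.fluxes[objective_reaction]
        samples.append(sol)
    if not samples:
        raise RuntimeError("no alternate-optima samples could be generated")
    return samples


@dataclass
class RegulationTarget:
    """A reaction whose flux range separates max-product from min-product states."""

    reaction: str
    direction: str  # up | down
    separation: float  # gap between the two flux ranges

    def __post_init__(self):
        if self.separation <= 0:
            raise ValueError("reported targets must have positive separation")


def regulation_targets(
    max_samples: list,
    min_samples: list,
    min_separation: float = FEASIBILITY_TOL,
) -> list:
    """Nominate up-/down-regulation targets from two alternate-optima sets.

    A reaction is an "up" target when every max-product sample carries more
    flux than any min-product sample (strictly separated ranges, the
    product-favoring flux higher), and a "down" target in the reverse case.
    Targets are sorted by separation, largest first.
    """
    if not max_samples or not min_samples:
        raise ValueError("both sample sets must be non-empty")
    rxns = set(max_samples[0].fluxes)
    for s in list(max_samples) + list(min_samples):
        if set(s.fluxes) != rxns:
            raise ValueError("samples cover different reaction sets")
    targets = []
    for rid in sorted(rxns):
        vmax = [s.fluxes[rid] for s in max_samples]
        vmin = [s.fluxes[rid] for s in min_samples]
        if min(vmax) > max(vmin) + min_separation:
            targets.append(RegulationTarget(rid, "up", min(vmax) - max(vmin)))
        elif max(vmax) < min(vmin) - min_separation:
            targets.append(RegulationTarget(rid, "down", min(vmin) - max(vmax)))
    targets.sort(key=lambda t: (-t.separation, t.reaction))
    return targets
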