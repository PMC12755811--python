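"""Flux balance analysis and related linear-programming procedures.

FBA finds a flux vector v maximizing (or minimizing) one reaction's flux
subject to steady state ``S v = 0`` and bounds ``lb <= v <= ub``.  Linear
programs are solved with HiGHS via :func:`scipy.optimize.linprog`; solves are
deterministic for a fixed model ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Medium, apply_medium, build_stoichiometric_matrix

__all__ = [
    "FluxDistribution",
    "RobustnessCurve",
    "ChemostatMeasurement",
    "fba",
    "fix_growth_fraction",
    "robustness",
    "chemostat_flux",
    "rescale_to_uptake",
    "atp_yield_per_glucose",
    "FEASIBILITY_TOL",
]

#: Steady-state / LP feasibility tolerance; fluxes below it count as zero.
FEASIBILITY_TOL = 1e-6


@dataclass
class FluxDistribution:
    """A flux vector with its objective value and solver status."""

    fluxes: dict
    objective_value: float
    status: str  # optimal | infeasible | unbounded
    objective_reaction: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)

    def as_vector(self, reaction_ids) -> np.ndarray:
        return np.array([self.fluxes.get(r, 0.0) for r in reaction_ids])

    def steady_state_residual(self, model: MetabolicModel) -> float:
        """max |S v| over metabolites — 0 at exact steady state."""
        S = build_stoichiometric_matrix(model)
        v = self.as_vector(model.reaction_ids)
        return float(np.abs(S @ v).max()) if S.size else 0.0


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    model: MetabolicModel,
    objective: dict,
    direction: str = "maximize",
    extra_bounds: dict | None = None,
) -> FluxDistribution:
    """Optimize a linear combination of fluxes subject to S v = 0 and bounds.

    ``objective`` maps reaction id to coefficient; ``extra_bounds`` optionally
    overrides (lb, ub) per reaction without touching the model.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    S = build_stoichiometric_matrix(model)
    rxn_ids = model.reaction_ids
    pos = {r: j for j, r in enumerate(rxn_ids)}
    c = np.zeros(len(rxn_ids))
    for rid, coef in objective.items():
        c[pos[rid]] = coef
    if direction == "maximize":
        c = -c
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            bounds[pos[rid]] = (lo, hi)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxDistribution({}, float("nan"), status)
    fluxes = dict(zip(rxn_ids, res.x))
    obj_value = float(sum(coef * fluxes[rid] for rid, coef in objective.items()))
    return FluxDistribution(fluxes, obj_value, "optimal")


def fba(
    model: MetabolicModel,
    objective_reaction: str | None = None,
    direction: str = "maximize",
) -> FluxDistribution:
    """Plain FBA: optimize one reaction's flux at steady state.

    Returns an optimal basic (vertex) solution; infeasible and unbounded
    models are reported via ``status``, never as silent zeros.
    """
    obj = objective_reaction or model.objective_reaction
    if not obj:
        raise ValueError("no objective reaction given and model declares none")
    model.reaction(obj)  # raises KeyError if absent
    sol = solve_lp(model, {obj: 1.0}, direction)
    sol.objective_reaction = obj
    return sol


def fix_growth_fraction(
    model: MetabolicModel,
    fraction: float,
    growth_reaction: str | None = None,
) -> MetabolicModel:
    """Pin growth to at least ``fraction`` of its optimum.

    Runs FBA on the growth (biomass) reaction, then returns a copy with that
    reaction bounded to [fraction * mu*, mu*].  With a subsequent FBA on a
    product reaction this reproduces the growth-constrained product optimum.
    """
    if not 0 < fraction <= 1:
        raise ValueError("growth fraction must be in (0, 1]")
    growth = growth_reaction or model.objective_reaction
    wt = fba(model, growth)
    if not wt.optimal:
        raise RuntimeError(f"parent model has no optimal growth solution ({wt.status})")
    mu = wt.objective_value
    out = model.copy()
    rxn = out.reaction(growth)
    rxn.lower_bound = fraction * mu
    rxn.upper_bound = mu
    return out


@dataclass
class RobustnessCurve:
    """Objective optimum as a function of one reaction's allowed flux."""

    varied_reaction: str
    target_reaction: str
    grid: list = field(default_factory=list)  # (bound, optimum-or-None), sorted

    def values(self) -> list:
        return [v for _, v in self.grid]


def robustness(
    model: MetabolicModel,
    target_reaction: str,
    varied_reaction: str,
    bounds_grid,
    fixed: bool = False,
) -> RobustnessCurve:
    """Sweep one reaction's allowance and re-maximize the target each time.

    By default each grid value sets the varied reaction's *lower bound* (an
    uptake allowance for exchanges, the conservative reading); with
    ``fixed=True`` the flux is pinned to the grid value.  Infeasible grid
    points are recorded as None.
    """
    model.reaction(target_reaction)
    varied = model.reaction(varied_reaction)
    points = []
    for b in sorted(bounds_grid):
        if fixed:
            extra = {varied_reaction: (b, b)}
        else:
            extra = {varied_reaction: (b, varied.upper_bound)}
        sol = solve_lp(model, {target_reaction: 1.0}, "maximize", extra_bounds=extra)
        points.append((float(b), sol.objective_value if sol.optimal else None))
    return RobustnessCurve(varied_reaction, target_reaction, points)


@dataclass
class ChemostatMeasurement:
    """One steady-state chemostat observation for a metabolite."""

    dilution_rate: float  # D, 1/h
    c_supernatant: float  # mmol/L
    c_feed: float  # mmol/L
    biomass: float  # gDCW/L

    def __post_init__(self):
        if self.dilution_rate < 0:
            raise ValueError("dilution rate must be non-negative")
        if self.biomass <= 0:
            raise ValueError("biomass concentration must be positive")


def chemostat_flux(m: ChemostatMeasurement) -> float:
    """Specific exchange flux q_i = D (C_supernatant - C_feed) / X_biomass.

    Negative values are uptake (the metabolite is depleted relative to the
    feed), positive values secretion, in mmol.gDCW^-1.h^-1.
    """
    return m.dilution_rate * (m.c_supernatant - m.c_feed) / m.biomass


def rescale_to_uptake(
    flux: FluxDistribution,
    uptake_reaction: str,
    target_uptake: float = 100.0,
) -> FluxDistribution:
    """Rescale a flux distribution to a reference substrate consumption rate.

    All fluxes are multiplied by ``target_uptake / |v_uptake|`` so that the
    uptake reaction consumes exactly ``target_uptake`` (typically 100 mmol
    glucose.gDCW^-1.h^-1).  Steady state is preserved by linearity.
    """
    v = flux.fluxes.get(uptake_reaction)
    if v is None:
        raise KeyError(f"no flux for reaction {uptake_reaction!r}")
    if abs(v) <= FEASIBILITY_TOL:
        raise ValueError(f"uptake flux of {uptake_reaction} is zero; cannot rescale")
    factor = target_uptake / abs(v)
    return FluxDistribution(
        fluxes={r: f * factor for r, f in flux.fluxes.items()},
        objective_value=flux.objective_value * factor,
        status=flux.status,
        objective_reaction=flux.objective_reaction,
    )


def atp_yield_per_glucose(
    model: MetabolicModel,
    maintenance_reaction: str = "ATPM",
    glucose_exchange: str = "EX_glc__D_e",
    growth_reaction: str | None = None,
    glucose_uptake: float = 1.0,
) -> float:
    """Moles of ATP extractable per mole of glucose, at zero growth.

    Growth is fixed to 0 and glucose uptake to exactly ``glucose_uptake``
    mmol.gDCW^-1.h^-1; the ATP-hydrolysis (maintenance) flux is then
    maximized and divided by the uptake, so the value measures pure catabolic
    ATP capacity per glucose (e.g. 2 for homolactic EMP fermentation, higher
    with respiration) independently of the uptake level.
    """
    model.reaction(maintenance_reaction)
    if glucose_uptake <= 0:
        raise ValueError("glucose uptake must be positive")
    growth = growth_reaction or model.objective_reaction
    extra = {
        glucose_exchange: (-glucose_uptake, -glucose_uptake),
        maintenance_reaction: (0.0, None),
    }
    if growth:
        extra[growth] = (0.0, 0.0)
    sol = solve_lp(model, {maintenance_reaction: 1.0}, "maximize", extra_bounds=extra)
    if not sol.optimal:
        raise RuntimeError(f"ATP yield LP not optimal: {sol.status}")
    return sol.objective_value / glucose_uptake


def fba_on_medium(
    model: MetabolicModel, medium: Medium, objective_reaction: str | None = None
) -> FluxDistribution:
    """Convenience: apply a medium, then run FBA."""
    return fba(apply_medium(model, medium), objective_reaction)
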