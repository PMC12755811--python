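"""Minimization of metabolic adjustment (MOMA).

MOMA predicts the flux state of a perturbed (e.g. gene-deleted) network as
the feasible point closest to a wild-type reference, instead of assuming the
mutant re-optimizes growth.  The quadratic mode minimizes the squared
Euclidean distance sum_i (v_i - v_i^ref)^2 (a strictly convex QP with a
unique solution, solved with OSQP); the linear mode minimizes the L1 distance
via an LP.

The wild-type reference itself is made deterministic by a parsimonious
secondary objective: among all max-growth optima the one with minimal total
absolute flux is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import osqp
import scipy.sparse as sp
from scipy.optimize import linprog

from .fba import FEASIBILITY_TOL, FluxDistribution, fba
from .model import MetabolicModel, build_stoichiometric_matrix

__all__ = ["MomaSolution", "reference_state", "moma"]


@dataclass
class MomaSolution:
    """A MOMA projection: the mutant flux state plus its distance to the reference."""

    fluxes: FluxDistribution
    distance: float
    mode: str
    reference_id: str = ""

    @property
    def optimal(self) -> bool:
        return self.fluxes.optimal


def reference_state(
    model: MetabolicModel, objective_reaction: str | None = None
) -> FluxDistribution:
    """Deterministic wild-type reference: max growth, then minimal total flux.

    The growth optimum of an FBA problem is typically degenerate; among the
    alternate optima the flux vector with minimal sum |v_i| (parsimonious
    FBA) is selected, which is unique up to LP degeneracy and independent of
    solver seed.
    """
    obj = objective_reaction or model.objective_reaction
    primary = fba(model, obj)
    if not primary.optimal:
        raise RuntimeError(f"model infeasible; no reference state ({primary.status})")
    mu = primary.objective_value

    # min sum t  s.t.  S v = 0, -t <= v <= t, v_obj = mu, model bounds
    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    rxn_ids = model.reaction_ids
    pos = {r: j for j, r in enumerate(rxn_ids)}
    # variables x = [v, t]
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    b_eq = np.zeros(S.shape[0])
    # v - t <= 0 and -v - t <= 0
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
    b_ub = np.zeros(2 * n)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    j = pos[obj]
    bounds[j] = (mu, mu)
    bounds += [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError("parsimonious reference LP failed")
    fluxes = dict(zip(rxn_ids, res.x[:n]))
    return FluxDistribution(fluxes, mu, "optimal", objective_reaction=obj)


def _quadratic_moma(model: MetabolicModel, ref: np.ndarray) -> tuple:
    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    P = sp.eye(n, format="csc") * 2.0
    q = -2.0 * ref
    A = sp.vstack([sp.csc_matrix(S), sp.eye(n)], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    solver = osqp.OSQP()
    solver.setup(
        P,
        q,
        A,
        l,
        u,
        verbose=False,
        eps_abs=1e-9,
        eps_rel=1e-9,
        eps_prim_inf=1e-10,
        max_iter=200000,
        polishing=True,
    )
    result = solver.solve(raise_error=False)
    status = result.info.status
    if "solved" not in status:
        return None, "infeasible" if "infeasible" in status else "infeasible"
    v = np.clip(result.x, lb, ub)  # polish leaves O(1e-12) bound noise
    return v, "optimal"


def _linear_moma(model: MetabolicModel, ref: np.ndarray) -> tuple:
    S = build_stoichiometric_matrix(model)
    n = len(model.reactions)
    # variables [v, t]; minimize sum t with t >= |v - ref|
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.hstack([S, np.zeros_like(S)])
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
    b_ub = np.concatenate([ref, -ref])
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions] + [(0, None)] * n
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        bounds=bounds, method="highs",
    )
    if res.status != 0:
        return None, "infeasible"
    return res.x[:n], "optimal"


def moma(
    perturbed_model: MetabolicModel,
    reference: FluxDistribution,
    mode: str = "quadratic",
) -> MomaSolution:
    """Project the reference flux state onto the perturbed model's flux space.

    Reactions absent from the reference are treated as reference flux 0.  The
    perturbed model's growth is read off the projection (it never exceeds the
    mutant's own FBA optimum).  Infeasible perturbed models are reported with
    status "infeasible" and undefined (NaN) distance.
    """
    if mode not in ("quadratic", "linear"):
        raise ValueError(f"unknown MOMA mode {mode!r}")
    rxn_ids = perturbed_model.reaction_ids
    ref = reference.as_vector(rxn_ids)
    solve = _quadratic_moma if mode == "quadratic" else _linear_moma
    v, status = solve(perturbed_model, ref)
    if status != "optimal":
        return MomaSolution(
            FluxDistribution({}, float("nan"), status), float("nan"), mode
        )
    if mode == "quadratic":
        distance = float(((v - ref) ** 2).sum())
    else:
        distance = float(np.abs(v - ref).sum())
    if distance < FEASIBILITY_TOL:
        distance = max(distance, 0.0)
    obj = reference.objective_reaction or perturbed_model.objective_reaction
    fluxes = dict(zip(rxn_ids, v))
    obj_value = fluxes.get(obj, float("nan"))
    sol = FluxDistribution(fluxes, obj_value, "optimal", objective_reaction=obj)
    return MomaSolution(sol, distance, mode, reference_id=reference.objective_reaction)
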