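"""Flux balance analysis: maximal-ATP linear programming and integrity checks.

The flux polytope is {v : S v = 0, lb <= v <= ub}. Maximizing the ATP
demand reaction over it is a plain LP, solved with the HiGHS solvers in
scipy. Note that at a degenerate optimum only the objective value is
well defined; the returned flux vector is one optimal vertex among many.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel, is_exchange, stoichiometric_matrix

DEFAULT_TOLERANCE = 1e-6


class InfeasibleModelError(RuntimeError):
    """Raised when an LP over the flux polytope has no feasible point."""


@dataclass
class FluxSolution:
    """Result of one flux-balance LP."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve_lp(
    S: np.ndarray,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
) -> tuple[str, np.ndarray | None, float | None]:
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, None, None
    return status, res.x, res.fun


def optimize(
    model: MetabolicModel,
    objective: str | None = None,
    maximize: bool = True,
) -> FluxSolution:
    """Optimize flux through one reaction subject to steady state and bounds."""
    objective = objective or model.objective_reaction
    if objective is None:
        raise ValueError("model has no objective reaction and none was given")
    model.reaction(objective)  # raises on unknown id
    S = stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    c = np.zeros(len(model.reactions))
    j = model.reaction_ids.index(objective)
    c[j] = -1.0 if maximize else 1.0
    status, x, fun = _solve_lp(S, bounds, c)
    if status != "optimal":
        return FluxSolution(objective_value=float("nan"), fluxes={}, status=status)
    return FluxSolution(
        objective_value=float(x[j]),
        fluxes=dict(zip(model.reaction_ids, map(float, x))),
        status="optimal",
    )


def fba_max_atp(
    model: MetabolicModel, tolerance: float = DEFAULT_TOLERANCE
) -> FluxSolution:
    """Maximize the ATP demand flux; the study's simulation objective."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    sol = optimize(model, maximize=True)
    if sol.optimal:
        S = stoichiometric_matrix(model)
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        residual = float(np.max(np.abs(S @ v))) if len(v) else 0.0
        if residual > max(tolerance, 1e-6):
            raise RuntimeError(
                f"solver returned a non-steady-state solution (|S v| = {residual:g})"
            )
    return sol


def _open_exchanges(model: MetabolicModel, bound: float = 1000.0) -> MetabolicModel:
    updates = {
        r.id: (-bound, max(r.upper_bound, bound))
        for r in model.reactions
        if is_exchange(r)
    }
    return model.with_bounds(updates)


@dataclass
class IntegrityReport:
    atp_producible: bool
    dead_ends: list[str]
    blocked_reactions: list[str]


def check_model_integrity(
    model: MetabolicModel, tolerance: float = DEFAULT_TOLERANCE
) -> IntegrityReport:
    """Can the network make ATP, and is it free of gaps?

    ATP producibility and blocked reactions are evaluated with every
    exchange opened in both directions, so the report describes the
    network's structure rather than any one diet.
    """
    from .core import find_dead_end_metabolites

    opened = _open_exchanges(model)
    sol = fba_max_atp(opened, tolerance)
    atp_ok = sol.optimal and sol.objective_value > tolerance
    fva = flux_variability(opened, fraction_of_optimum=0.0)
    blocked = [
        rxn_id
        for rxn_id, (lo, hi) in fva.items()
        if max(abs(lo), abs(hi)) < tolerance
    ]
    return IntegrityReport(
        atp_producible=bool(atp_ok),
        dead_ends=find_dead_end_metabolites(model),
        blocked_reactions=blocked,
    )


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
) -> dict[str, tuple[float, float]]:
    """Per-reaction flux range, optionally under near-optimality.

    With ``fraction_of_optimum`` f > 0 the objective flux is first
    pinned to >= f * optimum; two LPs per reaction then give its min and
    max flux.
    """
    if not 0 <= fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in [0, 1]")
    work = model
    if fraction_of_optimum > 0:
        if model.objective_reaction is None:
            raise ValueError("fraction_of_optimum > 0 requires an objective")
        sol = fba_max_atp(model)
        if not sol.optimal:
            raise InfeasibleModelError(f"model is {sol.status}; cannot run FVA")
        obj = model.reaction(model.objective_reaction)
        work = model.with_bounds(
            {obj.id: (fraction_of_optimum * sol.objective_value, obj.upper_bound)}
        )
    S = stoichiometric_matrix(work)
    bounds = [(r.lower_bound, r.upper_bound) for r in work.reactions]
    ranges: dict[str, tuple[float, float]] = {}
    c = np.zeros(len(work.reactions))
    for j, rxn_id in enumerate(work.reaction_ids):
        c[j] = 1.0
        status, x, _ = _solve_lp(S, bounds, c)
        if status != "optimal":
            raise InfeasibleModelError(f"FVA subproblem for {rxn_id} is {status}")
        lo = float(x[j])
        c[j] = -1.0
        status, x, _ = _solve_lp(S, bounds, c)
        if status != "optimal":
            raise InfeasibleModelError(f"FVA subproblem for {rxn_id} is {status}")
        hi = float(x[j])
        c[j] = 0.0
        ranges[rxn_id] = (lo, hi)
    return ranges
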