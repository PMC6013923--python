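"""ACHR sampling of the steady-state flux polytope.

Artificial-centering hit-and-run: warm-up points are stored as columns
of a matrix W with running center s; each iteration draws a random
warm-up column y, steps from the current point along the direction
(y - s)/||y - s|| by a length drawn uniformly on the feasible chord, and
substitutes the new point into W at a random column, recomputing the
center. Every ``steps_per_point``-th iterate is recorded.

Sampling runs in an orthonormal basis of the null space of S (plus any
fixed-flux equalities), so the steady-state condition holds to machine
precision and only the box bounds remain as inequalities. By default the
ATP demand is first constrained to >= 99% of its FBA maximum, so the
sampler characterizes the near-optimal flux space the simulations
describe; set ``fraction_of_optimum=None`` to sample the whole polytope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

from .core import MetabolicModel, stoichiometric_matrix
from .fba import InfeasibleModelError, fba_max_atp

_EPS_DIR = 1e-12
_CHORD_INSET = 1e-10


@dataclass(frozen=True)
class SamplerConfig:
    """ACHR run parameters.

    Defaults (2000 points, 500 iterations between recorded points)
    match the full-scale study protocol; ``n_warmup`` defaults to twice
    the null-space dimension with a floor of 200, capped at 5000.
    """

    n_points: int = 2000
    steps_per_point: int = 500
    n_warmup: int | None = None
    seed: int = 0
    tolerance: float = 1e-6
    fraction_of_optimum: float | None = 0.99

    def __post_init__(self) -> None:
        if self.n_points <= 0 or self.steps_per_point <= 0:
            raise ValueError("n_points and steps_per_point must be positive")
        if self.n_warmup is not None and self.n_warmup <= 0:
            raise ValueError("n_warmup must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.fraction_of_optimum is not None and not (
            0 <= self.fraction_of_optimum <= 1
        ):
            raise ValueError("fraction_of_optimum must be in [0, 1] or None")


@dataclass
class FluxSampleSet:
    """Sampled steady-state flux vectors for one condition.

    ``samples`` has one row per reaction (order ``reaction_ids``) and
    one column per recorded point, in mmol gDW^-1 h^-1.
    """

    diet_label: str
    reaction_ids: list[str]
    samples: np.ndarray
    config: SamplerConfig

    @property
    def n_points(self) -> int:
        return self.samples.shape[1]

    def fluxes(self, reaction_id: str) -> np.ndarray:
        try:
            return self.samples[self.reaction_ids.index(reaction_id)]
        except ValueError:
            raise KeyError(f"reaction {reaction_id!r} not in sample set") from None

    def validity(self, model: MetabolicModel) -> dict[str, float]:
        """Worst steady-state residual and bound violation over all samples."""
        S = stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        order = [self.reaction_ids.index(r) for r in model.reaction_ids]
        V = self.samples[order]
        residual = float(np.max(np.abs(S @ V))) if V.size else 0.0
        bound_violation = float(
            np.max(np.maximum(lb[:, None] - V, V - ub[:, None]).clip(min=0))
        ) if V.size else 0.0
        return {"max_steady_state_residual": residual,
                "max_bound_violation": bound_violation}


class _Polytope:
    """{v = v_p + N z : lb <= v <= ub} with N an orthonormal null-space basis."""

    def __init__(self, model: MetabolicModel, tolerance: float):
        self.reaction_ids = model.reaction_ids
        S = stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        fixed = ub - lb < 1e-12
        rows = [S]
        rhs = [np.zeros(S.shape[0])]
        if fixed.any():
            E = np.zeros((int(fixed.sum()), S.shape[1]))
            E[np.arange(int(fixed.sum())), np.where(fixed)[0]] = 1.0
            rows.append(E)
            rhs.append(lb[fixed])
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        self._S_eq = S
        self._b_eq = np.zeros(S.shape[0])
        self.v_p, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ self.v_p - b)) > tolerance:
            raise InfeasibleModelError(
                "fixed-flux constraints are inconsistent with steady state"
            )
        self.N = null_space(A)
        self.lb, self.ub = lb, ub
        self.dim = self.N.shape[1]
        self.tolerance = tolerance

    def to_flux(self, z: np.ndarray) -> np.ndarray:
        return self.v_p + self.N @ z

    def to_coords(self, v: np.ndarray) -> np.ndarray:
        return self.N.T @ (v - self.v_p)

    def interior_point(self) -> np.ndarray:
        """Feasible point pushed off the polytope faces (Chebyshev-style LP)."""
        from scipy.optimize import linprog

        n = len(self.lb)
        width = self.ub - self.lb
        active = width > 1e-12
        w = np.minimum(width, 1.0) / 2.0
        # variables (v, t): maximize t s.t. S v = 0, lb + w t <= v <= ub - w t
        A_rows = []
        b_rows = []
        for i in range(n):
            if not active[i]:
                continue
            row = np.zeros(n + 1)
            row[i] = -1.0
            row[n] = w[i]
            A_rows.append(row)          # -v_i + w t <= -lb_i
            b_rows.append(-self.lb[i])
            row = np.zeros(n + 1)
            row[i] = 1.0
            row[n] = w[i]
            A_rows.append(row)          # v_i + w t <= ub_i
            b_rows.append(self.ub[i])
        S_aug = np.hstack([self._S_eq, np.zeros((self._S_eq.shape[0], 1))])
        c = np.zeros(n + 1)
        c[n] = -1.0
        bounds = [(self.lb[i], self.ub[i]) for i in range(n)] + [(0, 1.0)]
        res = linprog(
            c, A_ub=np.array(A_rows), b_ub=np.array(b_rows),
            A_eq=S_aug, b_eq=self._b_eq, bounds=bounds, method="highs",
        )
        if res.status != 0:
            raise InfeasibleModelError("flux polytope is empty")
        v0 = res.x[:n]
        # exact projection onto the null-space parameterization
        return self.to_flux(self.to_coords(v0))

    def chord(self, z: np.ndarray, u: np.ndarray) -> tuple[float, float]:
        """Feasible step interval along direction u (z-space) from z."""
        v = self.to_flux(z)
        a = self.N @ u
        t_lo, t_hi = -np.inf, np.inf
        big = np.abs(a) > _EPS_DIR
        with np.errstate(divide="ignore", invalid="ignore"):
            upper = (self.ub - v)[big] / a[big]
            lower = (self.lb - v)[big] / a[big]
        pos = a[big] > 0
        hi_candidates = np.where(pos, upper, lower)
        lo_candidates = np.where(pos, lower, upper)
        if hi_candidates.size:
            t_hi = float(hi_candidates.min())
            t_lo = float(lo_candidates.max())
        return t_lo, t_hi

    def project_inside(self, z: np.ndarray) -> np.ndarray:
        """Clip to bounds and re-project into the null-space basis."""
        v = np.clip(self.to_flux(z), self.lb, self.ub)
        return self.to_coords(v)

    def violation(self, z: np.ndarray) -> float:
        v = self.to_flux(z)
        return float(np.max(np.maximum(self.lb - v, v - self.ub).clip(min=0)))


def _build_polytope(model: MetabolicModel, tolerance: float) -> _Polytope:
    return _Polytope(model, tolerance)


def _pin_to_optimum(model: MetabolicModel, fraction: float) -> MetabolicModel:
    if model.objective_reaction is None:
        raise ValueError("optimality-constrained sampling requires an objective")
    sol = fba_max_atp(model)
    if not sol.optimal:
        raise InfeasibleModelError(f"model is {sol.status}; cannot sample")
    obj = model.reaction(model.objective_reaction)
    return model.with_bounds(
        {obj.id: (fraction * sol.objective_value, obj.upper_bound)}
    )


def generate_warmup(
    model: MetabolicModel,
    n_warmup: int | None = None,
    seed: int = 0,
    tolerance: float = 1e-6,
) -> np.ndarray:
    """Warm-up matrix W (reactions x n_warmup) by basic hit-and-run.

    The chain starts at an interior LP solution and takes one
    uniform-random-direction step per stored point.
    """
    poly = _build_polytope(model, tolerance)
    W_z = _warmup_coords(poly, n_warmup, np.random.default_rng(seed))
    return poly.v_p[:, None] + poly.N @ W_z


def _warmup_coords(
    poly: _Polytope, n_warmup: int | None, rng: np.random.Generator
) -> np.ndarray:
    k = poly.dim
    if n_warmup is None:
        # floor of 200: with very few warm-up columns the direction set
        # (y - s) is too coarse and the chain's stationary distribution
        # is measurably non-uniform on low-dimensional polytopes
        n_warmup = min(max(2 * k, 200, k + 1), 5000)
    if k > 0 and n_warmup < k + 1:
        raise ValueError(
            f"n_warmup={n_warmup} is below the null-space dimension + 1 ({k + 1})"
        )
    z = poly.to_coords(poly.interior_point())
    if k == 0:
        return np.zeros((0, max(n_warmup, 1)))
    cols = [z.copy()]
    while len(cols) < n_warmup:
        u = rng.standard_normal(k)
        norm = np.linalg.norm(u)
        if norm < _EPS_DIR:
            continue
        u /= norm
        z = _step(poly, z, u, rng)
        cols.append(z.copy())
    return np.column_stack(cols)


def _step(
    poly: _Polytope, z: np.ndarray, u: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    t_lo, t_hi = poly.chord(z, u)
    if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
        return z
    span = t_hi - t_lo
    t = rng.uniform(t_lo + _CHORD_INSET * span, t_hi - _CHORD_INSET * span)
    z_new = z + t * u
    if poly.violation(z_new) > poly.tolerance:
        z_new = poly.project_inside(z_new)
        if poly.violation(z_new) > poly.tolerance:
            raise RuntimeError("persistent numerical escape from the flux polytope")
    return z_new


def achr_sample(
    model: MetabolicModel,
    config: SamplerConfig | None = None,
    diet_label: str = "",
) -> FluxSampleSet:
    """Sample the steady-state flux space of ``model`` with ACHR."""
    config = config or SamplerConfig()
    work = model
    if config.fraction_of_optimum is not None:
        work = _pin_to_optimum(model, config.fraction_of_optimum)
    rng = np.random.default_rng(config.seed)
    poly = _build_polytope(work, config.tolerance)
    k = poly.dim

    if k == 0:
        warnings.warn(
            "flux polytope has zero volume (all reactions fixed); "
            "returning the single feasible point",
            stacklevel=2,
        )
        v = poly.to_flux(np.zeros(0))
        samples = np.repeat(v[:, None], config.n_points, axis=1)
        return FluxSampleSet(diet_label, poly.reaction_ids, samples, config)

    W = _warmup_coords(poly, config.n_warmup, rng)
    n_w = W.shape[1]
    center = W.mean(axis=1)
    x = center.copy()

    recorded = np.empty((k, config.n_points))
    for p in range(config.n_points):
        for _ in range(config.steps_per_point):
            for _try in range(16):
                y = W[:, rng.integers(n_w)]
                direction = y - center
                norm = np.linalg.norm(direction)
                if norm > _EPS_DIR:
                    break
            else:
                continue  # degenerate W; keep current point
            x = _step(poly, x, direction / norm, rng)
            j = rng.integers(n_w)
            center += (x - W[:, j]) / n_w
            W[:, j] = x
        recorded[:, p] = x

    samples = poly.v_p[:, None] + poly.N @ recorded
    # snap residual round-off onto the box (validity contract: <= tolerance)
    np.clip(samples, poly.lb[:, None], poly.ub[:, None], out=samples)
    return FluxSampleSet(diet_label, poly.reaction_ids, samples, config)


def sample_diet_conditions(
    model_by_diet: dict[str, MetabolicModel],
    config: SamplerConfig | None = None,
) -> dict[str, FluxSampleSet]:
    """Run ACHR per diet-constrained model (same config/seed for each)."""
    config = config or SamplerConfig()
    return {
        name: achr_sample(m, config, diet_label=name)
        for name, m in model_by_diet.items()
    }
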