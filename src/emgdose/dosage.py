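"""Constrained allocation of a 60-minute therapy session over four exercises.

Predicted activation is condensed into a per-exercise profile: sᵢ, the
mean predicted normalized RMS of the three superficial muscles during
exercise i, and dᵢ the analogous mean over the three deep muscles. The
session plan x (minutes per exercise) minimizes

    f(x) = −ws·Σᵢ xᵢ sᵢ − wd·Σᵢ xᵢ dᵢ + λᵥ·Var(x)

subject to Σ xᵢ = 60 and 5 ≤ xᵢ ≤ 30, solved with SciPy's trust-region
constrained method from the equal split (15, 15, 15, 15). Var is the
population variance of the four minutes; its penalty (λᵥ = 0.1 by
default) discourages concentrating the whole session in one exercise.
This "goal-consistent" sign convention penalizes high variance; the
alternative ``sign_mode="literal"`` flips the variance term's sign
(−λᵥ·Var, which *rewards* spread under minimization) for comparison.

Three named weighting cases shift emphasis between superficial and deep
activation: 70/30, 50/50 and 30/70. An exhaustive lattice search
(:func:`grid_oracle`) provides an independent check of the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, minimize

from .cohort import MOVEMENTS, LAYER_MAP

__all__ = [
    "ActivationProfile",
    "AllocationWeights",
    "AllocationConstraints",
    "AllocationPlan",
    "NAMED_CASES",
    "activation_profile",
    "objective",
    "objective_gradient",
    "solve_allocation",
    "grid_oracle",
    "run_cases",
]

SIGN_MODES = ("goal-consistent", "literal")


@dataclass(frozen=True)
class ActivationProfile:
    """Per-exercise mean predicted activation, split by anatomical layer.

    ``s[i]`` / ``d[i]`` are the mean predicted normalized RMS of the
    superficial / deep muscle groups during exercise ``exercises[i]``;
    both are dimensionless in [0, 1]. Exercise order matches the movement
    label encoding.
    """

    s: np.ndarray
    d: np.ndarray
    exercises: tuple[str, ...] = MOVEMENTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "s", np.asarray(self.s, dtype=float))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        n = len(self.exercises)
        if self.s.shape != (n,) or self.d.shape != (n,):
            raise ValueError(f"profile needs {n} superficial and {n} deep means")
        for name, v in (("s", self.s), ("d", self.d)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} values must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class AllocationWeights:
    """Superficial/deep emphasis (ws, wd); named cases sum to one."""

    ws: float
    wd: float
    case_label: str = "custom"

    def __post_init__(self) -> None:
        if self.ws < 0 or self.wd < 0:
            raise ValueError("weights must be nonnegative")
        if self.case_label != "custom" and abs(self.ws + self.wd - 1.0) > 1e-9:
            raise ValueError(f"named case {self.case_label!r} requires ws + wd = 1")


NAMED_CASES: tuple[AllocationWeights, ...] = (
    AllocationWeights(0.7, 0.3, "70/30"),
    AllocationWeights(0.5, 0.5, "50/50"),
    AllocationWeights(0.3, 0.7, "30/70"),
)


@dataclass(frozen=True)
class AllocationConstraints:
    """Session structure: total minutes, per-exercise bounds, variance penalty."""

    total_minutes: float = 60.0
    lower_bound: float = 5.0
    upper_bound: float = 30.0
    variance_penalty: float = 0.1
    n_exercises: int = 4

    def __post_init__(self) -> None:
        if self.variance_penalty < 0:
            raise ValueError("variance_penalty must be nonnegative")
        if self.n_exercises < 1:
            raise ValueError("need at least one exercise")
        if not (
            self.n_exercises * self.lower_bound
            <= self.total_minutes
            <= self.n_exercises * self.upper_bound
        ):
            raise ValueError(
                f"infeasible constraints: need n·lower <= total <= n·upper, got "
                f"{self.n_exercises}·{self.lower_bound} <= {self.total_minutes} "
                f"<= {self.n_exercises}·{self.upper_bound}"
            )


@dataclass(frozen=True)
class AllocationPlan:
    """Optimized minutes per exercise plus the objective achieved."""

    x: np.ndarray
    objective_value: float
    weights: AllocationWeights
    exercises: tuple[str, ...] = MOVEMENTS
    sign_mode: str = "goal-consistent"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    @property
    def minutes_rounded(self) -> np.ndarray:
        """Whole-minute display allocation (invariants hold on raw x)."""
        return np.round(self.x).astype(int)

    def as_dict(self) -> dict:
        return {
            "case": self.weights.case_label,
            "ws": self.weights.ws,
            "wd": self.weights.wd,
            "sign_mode": self.sign_mode,
            "exercises": list(self.exercises),
            "minutes": [float(v) for v in self.x],
            "minutes_rounded": [int(v) for v in self.minutes_rounded],
            "objective_value": self.objective_value,
            "diagnostics": self.diagnostics,
        }


def activation_profile(
    predictions: pd.DataFrame,
    layer_map: Mapping[str, str] | None = None,
    movements: Sequence[str] = MOVEMENTS,
) -> ActivationProfile:
    """Condense pooled LOSO predictions into per-exercise (sᵢ, dᵢ) means.

    ``predictions`` must carry a ``movement_code`` column plus one
    predicted-normalized-RMS column per muscle. For each exercise, sᵢ is
    the mean over the superficial muscles of the mean prediction over that
    exercise's windows; dᵢ the same over deep muscles. An empty
    (muscle, movement) cell is an error.
    """
    layer_map = dict(layer_map or LAYER_MAP)
    superficial = [m for m, l in layer_map.items() if l == "superficial"]
    deep = [m for m, l in layer_map.items() if l == "deep"]
    missing = [m for m in superficial + deep if m not in predictions.columns]
    if missing:
        raise ValueError(f"predictions missing muscle columns: {missing}")
    s, d = [], []
    for code, movement in enumerate(movements):
        block = predictions[predictions["movement_code"] == code]
        if block.empty or block[superficial + deep].isna().all().any():
            raise ValueError(f"no predictions for movement {movement!r}")
        per_muscle = block[superficial + deep].mean()
        s.append(float(np.clip(per_muscle[superficial].mean(), 0.0, 1.0)))
        d.append(float(np.clip(per_muscle[deep].mean(), 0.0, 1.0)))
    return ActivationProfile(s=np.array(s), d=np.array(d), exercises=tuple(movements))


def _combined_coefficients(
    profile: ActivationProfile, weights: AllocationWeights
) -> np.ndarray:
    return weights.ws * profile.s + weights.wd * profile.d


def objective(
    x: np.ndarray | Sequence[float],
    profile: ActivationProfile,
    weights: AllocationWeights,
    constraints: AllocationConstraints = AllocationConstraints(),
    sign_mode: str = "goal-consistent",
) -> float:
    """Allocation objective, to be minimized.

    goal-consistent: −ws·Σxᵢsᵢ − wd·Σxᵢdᵢ + λᵥ·Var(x) (variance penalized);
    literal: the same with −λᵥ·Var(x). Var is the population variance.
    """
    if sign_mode not in SIGN_MODES:
        raise ValueError(f"unknown sign_mode {sign_mode!r}; valid: {SIGN_MODES}")
    x = np.asarray(x, dtype=float)
    if x.shape != (len(profile.exercises),):
        raise ValueError(
            f"allocation must have {len(profile.exercises)} entries, got shape {x.shape}"
        )
    c = _combined_coefficients(profile, weights)
    activation = float(c @ x)
    var = float(np.var(x))
    sign = 1.0 if sign_mode == "goal-consistent" else -1.0
    return -activation + sign * constraints.variance_penalty * var


def objective_gradient(
    x: np.ndarray,
    profile: ActivationProfile,
    weights: AllocationWeights,
    constraints: AllocationConstraints = AllocationConstraints(),
    sign_mode: str = "goal-consistent",
) -> np.ndarray:
    """Analytic gradient: −c + sign·λᵥ·(2/n)(x − x̄)."""
    x = np.asarray(x, dtype=float)
    c = _combined_coefficients(profile, weights)
    sign = 1.0 if sign_mode == "goal-consistent" else -1.0
    n = len(x)
    return -c + sign * constraints.variance_penalty * (2.0 / n) * (x - x.mean())


def solve_allocation(
    profile: ActivationProfile,
    weights: AllocationWeights,
    constraints: AllocationConstraints = AllocationConstraints(),
    sign_mode: str = "goal-consistent",
    x0: np.ndarray | None = None,
) -> AllocationPlan:
    """Minimize the allocation objective with trust-region constrained SQP.

    Starts from the equal split (total/n per exercise) unless ``x0`` is
    given; enforces the total-time equality and per-exercise bounds. The
    goal-consistent objective is convex (linear + λᵥ·Var), so the solver
    reaches the global optimum; the returned plan satisfies Σx = total
    within 1e-6 and the bounds, and never scores worse than the start.
    """
    n = constraints.n_exercises
    if len(profile.exercises) != n:
        raise ValueError(
            f"profile has {len(profile.exercises)} exercises, constraints expect {n}"
        )
    equal_split = np.full(n, constraints.total_minutes / n)
    start = equal_split if x0 is None else np.asarray(x0, dtype=float)
    # Hessian of the variance term is constant: sign·λᵥ·(2/n)(I − 11ᵀ/n)
    sign = 1.0 if sign_mode == "goal-consistent" else -1.0
    hess_const = (
        sign * constraints.variance_penalty * (2.0 / n)
        * (np.eye(n) - np.ones((n, n)) / n)
    )
    res = minimize(
        objective,
        start,
        args=(profile, weights, constraints, sign_mode),
        jac=objective_gradient,
        hess=lambda x, *a: hess_const,
        method="trust-constr",
        constraints=[LinearConstraint(np.ones(n), constraints.total_minutes,
                                      constraints.total_minutes)],
        bounds=Bounds(
            np.full(n, constraints.lower_bound), np.full(n, constraints.upper_bound)
        ),
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
    )
    x = np.clip(res.x, constraints.lower_bound, constraints.upper_bound)
    # re-project the tiny clip/solver drift back onto the equality constraint
    free = (x > constraints.lower_bound + 1e-9) & (x < constraints.upper_bound - 1e-9)
    deficit = constraints.total_minutes - x.sum()
    if abs(deficit) > 0 and free.any():
        x[free] += deficit / free.sum()
    value = objective(x, profile, weights, constraints, sign_mode)
    start_value = objective(start, profile, weights, constraints, sign_mode)
    if value > start_value + 1e-9:  # pragma: no cover - convex problem
        x, value = start, start_value
    return AllocationPlan(
        x=x,
        objective_value=value,
        weights=weights,
        exercises=profile.exercises,
        sign_mode=sign_mode,
        diagnostics={
            "iterations": int(res.niter),
            "constraint_violation": float(abs(x.sum() - constraints.total_minutes)),
            "solver_status": int(res.status),
        },
    )


def grid_oracle(
    profile: ActivationProfile,
    weights: AllocationWeights,
    constraints: AllocationConstraints = AllocationConstraints(),
    sign_mode: str = "goal-consistent",
    resolution: float = 0.5,
) -> AllocationPlan:
    """Exhaustive search on the feasible lattice with the given step.

    Enumerates all allocations with each xᵢ on the ``resolution`` grid in
    [lower, upper] and Σx = total, returning the lattice minimizer. An
    independent, brute-force check of the solver — intended for tests.
    """
    if sign_mode not in SIGN_MODES:
        raise ValueError(f"unknown sign_mode {sign_mode!r}; valid: {SIGN_MODES}")
    n = constraints.n_exercises
    lo, hi = constraints.lower_bound, constraints.upper_bound
    values = np.arange(lo, hi + resolution / 2, resolution)
    # enumerate n-1 coordinates on the grid, close the simplex with the last
    grids = np.meshgrid(*([values] * (n - 1)), indexing="ij")
    head = np.stack([g.ravel() for g in grids], axis=1)
    last = constraints.total_minutes - head.sum(axis=1)
    on_grid = np.abs((last - lo) / resolution - np.round((last - lo) / resolution)) < 1e-9
    feasible = (last >= lo - 1e-9) & (last <= hi + 1e-9) & on_grid
    if not feasible.any():
        raise ValueError("empty feasible lattice; check resolution and bounds")
    lattice = np.column_stack([head[feasible], last[feasible]])
    c = _combined_coefficients(profile, weights)
    sign = 1.0 if sign_mode == "goal-consistent" else -1.0
    vals = -(lattice @ c) + sign * constraints.variance_penalty * lattice.var(axis=1)
    best = int(np.argmin(vals))
    best_x, best_val = lattice[best], float(vals[best])
    return AllocationPlan(
        x=best_x,
        objective_value=best_val,
        weights=weights,
        exercises=profile.exercises,
        sign_mode=sign_mode,
        diagnostics={"method": "grid", "resolution": resolution},
    )


def run_cases(
    profile: ActivationProfile,
    constraints: AllocationConstraints = AllocationConstraints(),
    sign_mode: str = "goal-consistent",
    cases: Sequence[AllocationWeights] = NAMED_CASES,
) -> list[AllocationPlan]:
    """Solve the allocation for each named superficial/deep weighting case."""
    return [
        solve_allocation(profile, w, constraints, sign_mode=sign_mode) for w in cases
    ]
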