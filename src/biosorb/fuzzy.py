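"""Possibilistic (Tanaka-style) fuzzy linear regression with crisp data.

The model attaches a symmetric triangular fuzzy coefficient
``A_j = (a_j, c_j)`` (center, spread) to each predictor.  Fitting
minimises the total spread

    J = c_0 + c_1 + ... + c_n

subject to every observation lying inside the fuzzy prediction band at
membership level H (the *h-certain factor*):

    a_0 + sum_j a_j x_ij - (1-H) (c_0 + sum_j c_j |x_ij|) <= y_i
    a_0 + sum_j a_j x_ij + (1-H) (c_0 + sum_j c_j |x_ij|) >= y_i

with c_j >= 0 and the centers a_j free.  This is a linear program; it is
solved here with HiGHS through :func:`scipy.optimize.linprog`.  Raising H
tightens the inclusion requirement and can only inflate J.

Because the optimum can be non-unique (notably when J = 0), a secondary
LP picks, among the minimal-J solutions, the one with the smallest
L1-norm center vector, so repeated fits are reproducible.

A brute-force vertex-enumeration oracle (:func:`lp_oracle_small`) solves
the same program by exhaustive enumeration on tiny instances; it exists
to verify the LP route and is independent of it.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linprog

from .errors import (
    InvalidLevelError,
    OracleSizeError,
    ShapeError,
    SolverError,
    UndefinedR2Error,
)

__all__ = [
    "RegressionData",
    "FuzzyCoefficient",
    "FuzzyLinearModel",
    "fit_tanaka",
    "predict_interval",
    "ols_r_squared",
    "lp_oracle_small",
]

# LP numerical policy: feasibility checked to 1e-8 in the response units;
# HiGHS run at tightened tolerances (deterministic, so fits are repeatable).
FEAS_TOL = 1e-8
_HIGHS_OPTS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}


@dataclass(frozen=True)
class RegressionData:
    """Crisp regression data: predictor matrix x (N, n) and response y (N,)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if x.shape[0] == 1 and np.asarray(self.y).size != 1:
            x = x.T
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape[0] != y.shape[0]:
            raise ShapeError(f"x has {x.shape[0]} rows but y has {y.shape[0]}")
        if y.shape[0] < 2:
            raise ShapeError("need at least 2 observations")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ShapeError("all values must be finite")

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.x.shape[1]

    @classmethod
    def from_xy(cls, x, y) -> "RegressionData":
        """Build from 1-D predictor and response sequences."""
        return cls(np.asarray(x, dtype=float).reshape(-1, 1), np.asarray(y, dtype=float))


@dataclass(frozen=True)
class FuzzyCoefficient:
    """Symmetric triangular fuzzy number: center a_j and spread c_j >= 0."""

    center: float
    spread: float

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError(f"spread must be >= 0, got {self.spread}")

    @property
    def support(self) -> tuple[float, float]:
        """Membership-level-0 interval [center - spread, center + spread]."""
        return (self.center - self.spread, self.center + self.spread)


@dataclass(frozen=True)
class FuzzyLinearModel:
    """A fitted fuzzy regression: coefficients (index 0 = intercept), H, J."""

    coefficients: tuple[FuzzyCoefficient, ...]
    H: float
    J: float
    weighted: bool = field(default=False)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.center for c in self.coefficients])

    @property
    def spreads(self) -> np.ndarray:
        return np.array([c.spread for c in self.coefficients])

    @property
    def n_predictors(self) -> int:
        return len(self.coefficients) - 1

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "spreads": self.spreads.tolist(),
            "H": self.H,
            "J": self.J,
            "weighted": self.weighted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyLinearModel":
        coeffs = tuple(
            FuzzyCoefficient(a, c) for a, c in zip(d["centers"], d["spreads"])
        )
        return cls(coeffs, H=d["H"], J=d["J"], weighted=d.get("weighted", False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FuzzyLinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _design(data: RegressionData) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones(data.n_obs), data.x])
    return X, np.abs(X)


def _inclusion_rows(X, A, y, H):
    """Stacked A_ub z <= b_ub rows for the band-inclusion constraints.

    Variable order z = [a_0..a_n, c_0..c_n].
    """
    f = 1.0 - H
    A_ub = np.vstack([np.hstack([X, -f * A]), np.hstack([-X, -f * A])])
    b_ub = np.concatenate([y, -y])
    return A_ub, b_ub


def fit_tanaka(
    data: RegressionData, H: float = 0.0, weighted: bool = False
) -> FuzzyLinearModel:
    """Fit the fuzzy linear model at h-certain level H by linear programming.

    Parameters
    ----------
    data : RegressionData
        Crisp observations.
    H : float
        Membership level in [0, 1) at which inclusion is enforced.
    weighted : bool
        If True, minimise the data-weighted spread sum
        ``sum_j (sum_i |x_ij|) c_j`` (Tanaka's original objective) instead
        of the plain ``sum_j c_j``.  Default False.

    Returns
    -------
    FuzzyLinearModel
        Minimal-J feasible model; among ties, the minimum-L1-norm centers.
    """
    if not (0.0 <= H < 1.0):
        raise InvalidLevelError(f"H must be in [0, 1), got {H}")
    X, A = _design(data)
    y = data.y
    k = X.shape[1]
    A_ub, b_ub = _inclusion_rows(X, A, y, H)
    spread_cost = A.sum(axis=0) if weighted else np.ones(k)
    cost = np.concatenate([np.zeros(k), spread_cost])
    bounds = [(None, None)] * k + [(0, None)] * k
    res = linprog(cost, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs",
                  options=_HIGHS_OPTS)
    if not res.success:
        raise SolverError(f"LP failed (status {res.status}): {res.message}")
    j_star = float(res.fun)

    # Secondary solve: among solutions with (weighted) spread cost <= J* + tol,
    # minimise sum |a_j| via auxiliary variables t_j >= |a_j|.  The budget
    # slack must be tiny, or the tie-break could buy center-norm reductions
    # by inflating spreads.
    tol = 1e-12 * (1.0 + abs(j_star))
    n_rows = A_ub.shape[0]
    A2 = np.hstack([A_ub, np.zeros((n_rows, k))])
    budget = np.concatenate([np.zeros(k), spread_cost, np.zeros(k)])
    I = np.eye(k)
    Z = np.zeros((k, k))
    abs_lo = np.hstack([I, Z, -I])   # a_j - t_j <= 0
    abs_hi = np.hstack([-I, Z, -I])  # -a_j - t_j <= 0
    A2_ub = np.vstack([A2, budget, abs_lo, abs_hi])
    b2_ub = np.concatenate([b_ub, [j_star + tol], np.zeros(2 * k)])
    cost2 = np.concatenate([np.zeros(2 * k), np.ones(k)])
    bounds2 = bounds + [(0, None)] * k
    res2 = linprog(cost2, A_ub=A2_ub, b_ub=b2_ub, bounds=bounds2, method="highs",
                   options=_HIGHS_OPTS)
    if res2.success:
        a = res2.x[:k]
        c = np.maximum(res2.x[k : 2 * k], 0.0)
    else:  # fall back to the primary solution
        a = res.x[:k]
        c = np.maximum(res.x[k:], 0.0)
    coeffs = tuple(FuzzyCoefficient(float(ai), float(ci)) for ai, ci in zip(a, c))
    return FuzzyLinearModel(coeffs, H=float(H), J=float(np.sum(c)), weighted=weighted)


def predict_interval(model: FuzzyLinearModel, x) -> tuple[float, float]:
    """Predicted band [y_hat - w, y_hat + w] at predictor vector x.

    y_hat = a_0 + sum a_j x_j; half-width w = (1-H)(c_0 + sum c_j |x_j|).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape[0] != model.n_predictors:
        raise ShapeError(
            f"model has {model.n_predictors} predictors, got vector of length {x.shape[0]}"
        )
    xe = np.concatenate([[1.0], x])
    center = float(model.centers @ xe)
    half = float((1.0 - model.H) * (model.spreads @ np.abs(xe)))
    return (center - half, center + half)


def ols_r_squared(data: RegressionData) -> float:
    """Ordinary least-squares coefficient of determination of y on x.

    The crisp goodness-of-fit reported alongside the fuzzy fit.
    """
    if data.n_obs < 3:
        raise ShapeError("need at least 3 observations for R^2")
    y = data.y
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedR2Error("R^2 undefined for constant response")
    X, _ = _design(data)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ beta) ** 2))
    return 1.0 - sse / sst


def lp_oracle_small(data: RegressionData, H: float = 0.0) -> FuzzyLinearModel:
    """Solve the Tanaka LP by exhaustive vertex enumeration (test oracle).

    Enumerates every intersection of 2(n+1) constraint hyperplanes (band
    inclusion rows plus spread non-negativity), keeps the feasible ones and
    returns the vertex with minimal J.  Limited to <= 6 observations and
    <= 2 predictors; intended only for verification at tiny size.
    """
    if not (0.0 <= H < 1.0):
        raise InvalidLevelError(f"H must be in [0, 1), got {H}")
    if data.n_obs > 6 or data.n_predictors > 2:
        raise OracleSizeError(
            f"oracle limited to <=6 obs / <=2 predictors, got "
            f"{data.n_obs} obs, {data.n_predictors} predictors"
        )
    X, A = _design(data)
    y = data.y
    k = X.shape[1]
    m = 2 * k  # number of variables [a, c]
    A_ub, b_ub = _inclusion_rows(X, A, y, H)
    nonneg = np.hstack([np.zeros((k, k)), -np.eye(k)])
    G = np.vstack([A_ub, nonneg])
    h = np.concatenate([b_ub, np.zeros(k)])

    best_J = np.inf
    best_z = None
    n_rows = G.shape[0]
    for idx in itertools.combinations(range(n_rows), m):
        Gs = G[list(idx)]
        if np.linalg.matrix_rank(Gs) < m:
            continue
        z = np.linalg.solve(Gs, h[list(idx)])
        scale = 1.0 + np.max(np.abs(h)) + np.max(np.abs(z))
        if np.any(G @ z > h + FEAS_TOL * scale):
            continue
        J = float(np.sum(z[k:]))
        if J < best_J - 1e-12:
            best_J = J
            best_z = z
    if best_z is None:
        raise SolverError("oracle found no feasible vertex")
    a, c = best_z[:k], np.maximum(best_z[k:], 0.0)
    coeffs = tuple(FuzzyCoefficient(float(ai), float(ci)) for ai, ci in zip(a, c))
    return FuzzyLinearModel(coeffs, H=float(H), J=float(np.sum(c)))
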