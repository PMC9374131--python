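"""Inverse reward-value model of bar-release error rates, with satiation discounting.

The behavioral index of motivation in the cued reward-size task is the error
rate ``E`` — the proportion of trials on which the bar release misses the
accept window.  Error rate falls with the value of the upcoming reward.  The
basic model makes ``E`` inverse in cued reward size ``R`` (drops):

    E(R) = c / R + b

where ``c`` scales the incentive effect and ``b`` is a value-independent
baseline lapse rate.  Satiation discounts reward value exponentially in the
normalized cumulative reward ``Rcum`` consumed so far in the session:

    F(Rcum) = exp(-lambda * Rcum),          V = R * F(Rcum)
    E(R, Rcum) = c / (R * F(Rcum)) + b

so with ``lambda > 0`` the same cued amount supports less motivation late in
a session and error rates rise.  (An alternative reading of the discounted
model, ``(c/R + b) * F``, would make error rates *fall* with satiation and is
deliberately not used; see the module notes in docs/methods.md.)

Models are fitted to per-cell empirical error rates by plain (unweighted)
sum-of-squares minimization: a deterministic coarse grid search followed by
bounded local refinement from the best grid points.  The estimators follow
scikit-learn conventions (``fit``/``predict``, ``get_params``, fitted
attributes with trailing underscores) and compose with sklearn tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "ValueModelParams",
    "FitResult",
    "NonIdentifiableError",
    "predict_error_rate",
    "satiation_factor",
    "predict_error_rate_satiation",
    "RewardSizeErrorModel",
    "SatiationErrorModel",
    "fit_reward_size_model",
    "fit_satiation_model",
    "fit_by_group",
    "sse_on_grid",
]

# parameter bounds shared by grid search and local refinement
C_MAX = 10.0
LAMBDA_MAX = 20.0


class NonIdentifiableError(ValueError):
    """Raised when a table cannot pin down the model parameters."""


@dataclass(frozen=True)
class ValueModelParams:
    """Constants of the inverse reward-value model.

    c : incentive scale (drops * probability), >= 0
    b : baseline error rate, in [0, 1]
    lambda_ : satiation discount rate per unit normalized cumulative
        reward, >= 0 (0 disables satiation)
    """

    c: float
    b: float
    lambda_: float = 0.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")
        if self.lambda_ < 0:
            raise ValueError(f"lambda_ must be >= 0, got {self.lambda_}")


@dataclass
class FitResult:
    """Outcome of a sum-of-squares model fit."""

    params: ValueModelParams
    sse: float
    n_points: int
    predictions: np.ndarray
    converged: bool
    n_starts: int
    bounds_hit: dict[str, bool] = field(default_factory=dict)
    clipped_fraction: float = 0.0


def _check_reward(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("reward size R must be > 0")
    return R


def _check_rcum(rcum) -> np.ndarray:
    rcum = np.asarray(rcum, dtype=float)
    if np.any(~((rcum >= 0) & (rcum <= 1))):  # also catches NaN
        raise ValueError("normalized cumulative reward must lie in [0, 1]")
    return rcum


def predict_error_rate(params: ValueModelParams, R) -> np.ndarray | float:
    """Error rate E = clip(c/R + b, 0, 1) for reward size ``R`` (drops)."""
    R = _check_reward(R)
    out = np.clip(params.c / R + params.b, 0.0, 1.0)
    return out if out.ndim else float(out)


def satiation_factor(lambda_: float, rcum) -> np.ndarray | float:
    """Exponentially decaying reward value F(Rcum) = exp(-lambda * Rcum)."""
    if lambda_ < 0:
        raise ValueError("lambda_ must be >= 0")
    rcum = _check_rcum(rcum)
    out = np.exp(-lambda_ * rcum)
    return out if out.ndim else float(out)


def predict_error_rate_satiation(params: ValueModelParams, R, rcum) -> np.ndarray | float:
    """Error rate under satiation-discounted value V = R * F(Rcum).

    E = clip(c / (R * F) + b, 0, 1); reduces to :func:`predict_error_rate`
    exactly when ``lambda_ == 0``.
    """
    R = _check_reward(R)
    rcum = _check_rcum(rcum)
    value = R * np.exp(-params.lambda_ * rcum)
    out = np.clip(params.c / value + params.b, 0.0, 1.0)
    return out if out.ndim else float(out)


def _raw_prediction(c, b, lam, R, rcum):
    # unclipped model surface; broadcasting-friendly for grid search
    return c / (R * np.exp(-lam * rcum)) + b


def sse_on_grid(R, rcum, y, c_grid, b_grid, lambda_grid) -> tuple[np.ndarray, tuple]:
    """Sum of squared residuals on a full (c, b, lambda) grid.

    Returns the SSE array of shape (len(c), len(b), len(lambda)) and the
    index of its minimum.  Predictions are clipped to [0, 1] exactly as in
    :func:`predict_error_rate_satiation`.
    """
    R = np.asarray(R, float)
    rcum = np.asarray(rcum, float)
    y = np.asarray(y, float)
    c = np.asarray(c_grid, float)[:, None, None, None]
    b = np.asarray(b_grid, float)[None, :, None, None]
    lam = np.asarray(lambda_grid, float)[None, None, :, None]
    pred = np.clip(_raw_prediction(c, b, lam, R, rcum), 0.0, 1.0)
    sse = np.sum((pred - y) ** 2, axis=-1)
    idx = np.unravel_index(np.argmin(sse), sse.shape)
    return sse, idx


def _refine(start, free_lambda, R, rcum, y):
    """Bounded local least-squares refinement from one start point."""
    if free_lambda:
        x0 = np.asarray(start, float)
        lb = [0.0, 0.0, 0.0]
        ub = [C_MAX, 1.0, LAMBDA_MAX]
    else:
        x0 = np.asarray(start[:2], float)
        lb = [0.0, 0.0]
        ub = [C_MAX, 1.0]
    fixed_lam = 0.0 if free_lambda else start[2]

    def resid(x):
        c, b = x[0], x[1]
        lam = x[2] if free_lambda else fixed_lam
        return np.clip(_raw_prediction(c, b, lam, R, rcum), 0.0, 1.0) - y

    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                        ftol=1e-12, xtol=1e-12, gtol=1e-12)
    c, b = sol.x[0], sol.x[1]
    lam = sol.x[2] if free_lambda else fixed_lam
    sse = float(np.sum(resid(sol.x) ** 2))
    return (c, b, lam), sse, bool(sol.success)


class SatiationErrorModel(RegressorMixin, BaseEstimator):
    """Satiation-discounted inverse reward-value error model.

    Fits (c, b, lambda) to empirical error rates by unweighted SSE, using a
    deterministic coarse grid followed by bounded local refinement from the
    best ``n_starts`` grid points.  Ties among equal-SSE optima are broken by
    the smallest lambda, then the smallest c.

    Parameters
    ----------
    fix_lambda : float or None
        If a number, lambda is held at that value (0.0 recovers the pure
        reward-size model) and only (c, b) are optimized.
    n_grid_c, n_grid_b, n_grid_lambda : grid resolution.  c is log-spaced
        (with 0 included), b and lambda linear.
    n_starts : number of best grid points passed to local refinement.

    Attributes (after fit)
    ----------------------
    c_, b_, lambda_ : fitted constants.
    sse_ : sum of squared residuals at the optimum.
    n_points_ : number of fitted cells.
    converged_ : True if any refinement run converged.
    bounds_hit_ : dict flagging parameters that landed on a bound.
    clipped_fraction_ : fraction of fitted predictions that were clipped.

    Input ``X`` may be a DataFrame with columns ``reward_size`` (and
    ``quartile_rcum`` or ``rcum`` unless lambda is fixed at 0) or an array
    with columns (R, rcum).
    """

    _requires_rcum = True

    def __init__(self, fix_lambda: float | None = None, n_grid_c: int = 60,
                 n_grid_b: int = 41, n_grid_lambda: int = 41, n_starts: int = 5,
                 clip_warn_fraction: float = 0.2):
        self.fix_lambda = fix_lambda
        self.n_grid_c = n_grid_c
        self.n_grid_b = n_grid_b
        self.n_grid_lambda = n_grid_lambda
        self.n_starts = n_starts
        self.clip_warn_fraction = clip_warn_fraction

    # -- input handling -------------------------------------------------
    def _split_X(self, X):
        if isinstance(X, pd.DataFrame):
            R = X["reward_size"].to_numpy(float)
            rcum = None
            for col in ("quartile_rcum", "rcum"):
                if col in X.columns and X[col].notna().all():
                    rcum = X[col].to_numpy(float)
                    break
            if rcum is None:
                if self._needs_rcum():
                    raise ValueError(
                        "X needs a complete 'quartile_rcum' or 'rcum' column")
                rcum = np.zeros_like(R)
        else:
            X = np.asarray(X, float)
            if X.ndim == 1:
                R, rcum = X, np.zeros_like(X)
            else:
                R = X[:, 0]
                rcum = X[:, 1] if X.shape[1] > 1 else np.zeros(len(X))
        return _check_reward(R), _check_rcum(rcum)

    def _needs_rcum(self):
        return self._requires_rcum and self.fix_lambda is None

    def _check_identifiable(self, R, rcum):
        n_R = len(np.unique(R))
        if self.fix_lambda is None:
            n_q = len(np.unique(rcum))
            if n_R < 2 or n_q < 2:
                raise NonIdentifiableError(
                    f"satiation fit needs >= 2 reward sizes and >= 2 Rcum levels; "
                    f"got {n_R} reward sizes, {n_q} Rcum levels")
        elif n_R < 3:
            raise NonIdentifiableError(
                f"reward-size fit needs >= 3 distinct reward sizes, got {n_R}")

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        R, rcum = self._split_X(X)
        y = np.asarray(y, float)
        if y.shape != R.shape:
            raise ValueError("y must have one error rate per row of X")
        if np.any((y < 0) | (y > 1)):
            raise ValueError("observed error rates must lie in [0, 1]")
        self._check_identifiable(R, rcum)

        free_lambda = self.fix_lambda is None
        c_grid = np.concatenate([[0.0], np.geomspace(1e-3, C_MAX, self.n_grid_c - 1)])
        b_grid = np.linspace(0.0, 1.0, self.n_grid_b)
        if free_lambda:
            l_grid = np.linspace(0.0, LAMBDA_MAX, self.n_grid_lambda)
        else:
            l_grid = np.array([float(self.fix_lambda)])

        sse, _ = sse_on_grid(R, rcum, y, c_grid, b_grid, l_grid)
        flat_order = np.argsort(sse, axis=None, kind="stable")[: self.n_starts]
        starts = [
            (c_grid[i], b_grid[j], l_grid[k])
            for i, j, k in zip(*np.unravel_index(flat_order, sse.shape))
        ]

        candidates = []
        any_converged = False
        for s in starts:
            p, s_sse, ok = _refine(s, free_lambda, R, rcum, y)
            any_converged = any_converged or ok
            candidates.append((p, s_sse))
        # deterministic tie-break: SSE, then lambda, then c
        candidates.sort(key=lambda t: (round(t[1], 12), t[0][2], t[0][0]))
        (c, b, lam), best_sse = candidates[0]

        self.c_, self.b_, self.lambda_ = float(c), float(b), float(lam)
        self.sse_ = best_sse
        self.n_points_ = len(y)
        self.converged_ = any_converged
        self.n_starts_ = len(starts)
        tol = 1e-9
        self.bounds_hit_ = {
            "c": bool(c <= tol or c >= C_MAX - tol),
            "b": bool(b <= tol or b >= 1.0 - tol),
            "lambda": bool(free_lambda and (lam >= LAMBDA_MAX - tol)),
        }
        raw = _raw_prediction(c, b, lam, R, rcum)
        self.clipped_fraction_ = float(np.mean((raw < 0) | (raw > 1)))
        if self.clipped_fraction_ > self.clip_warn_fraction:
            warnings.warn(
                f"{self.clipped_fraction_:.0%} of fitted predictions were clipped "
                "to [0, 1]; parameter estimates may be poorly constrained",
                stacklevel=2)
        return self

    def predict(self, X):
        if not hasattr(self, "c_"):
            raise AttributeError("model is not fitted yet; call fit first")
        R, rcum = self._split_X(X)
        return np.clip(_raw_prediction(self.c_, self.b_, self.lambda_, R, rcum), 0.0, 1.0)

    @property
    def params_(self) -> ValueModelParams:
        return ValueModelParams(c=self.c_, b=self.b_, lambda_=self.lambda_)


class RewardSizeErrorModel(SatiationErrorModel):
    """Inverse reward-size error model E = c/R + b (no satiation term).

    Equivalent to :class:`SatiationErrorModel` with lambda fixed at 0; kept
    as a distinct estimator because it is the model fitted to whole-session
    error rates, where no Rcum covariate exists.
    """

    _requires_rcum = False

    def __init__(self, n_grid_c: int = 60, n_grid_b: int = 41, n_starts: int = 5,
                 clip_warn_fraction: float = 0.2):
        super().__init__(fix_lambda=0.0, n_grid_c=n_grid_c, n_grid_b=n_grid_b,
                         n_grid_lambda=1, n_starts=n_starts,
                         clip_warn_fraction=clip_warn_fraction)

    # sklearn get_params introspects __init__, so re-declare the signature
    def get_params(self, deep=True):
        return {"n_grid_c": self.n_grid_c, "n_grid_b": self.n_grid_b,
                "n_starts": self.n_starts,
                "clip_warn_fraction": self.clip_warn_fraction}


def _result_from(est: SatiationErrorModel, X) -> FitResult:
    return FitResult(
        params=est.params_,
        sse=est.sse_,
        n_points=est.n_points_,
        predictions=est.predict(X),
        converged=est.converged_,
        n_starts=est.n_starts_,
        bounds_hit=dict(est.bounds_hit_),
        clipped_fraction=est.clipped_fraction_,
    )


def fit_reward_size_model(table: pd.DataFrame, response: str = "error_rate") -> FitResult:
    """Fit E = c/R + b to an error-rate table by sum-of-squares.

    ``table`` needs columns ``reward_size`` and ``response``; each row is one
    residual (one session x reward-size cell).  Requires at least three
    distinct reward sizes.
    """
    est = RewardSizeErrorModel().fit(table, table[response].to_numpy(float))
    return _result_from(est, table)


def fit_satiation_model(table: pd.DataFrame, response: str = "error_rate",
                        fix_lambda: float | None = None) -> FitResult:
    """Fit E = c/(R * exp(-lambda*Rcum)) + b to a quartile error-rate table.

    ``table`` needs columns ``reward_size``, ``quartile_rcum`` (or ``rcum``)
    and ``response``; each (session, reward size, quartile) cell is one
    residual.
    """
    est = SatiationErrorModel(fix_lambda=fix_lambda)
    est.fit(table, table[response].to_numpy(float))
    return _result_from(est, table)


def fit_by_group(table: pd.DataFrame, model: str = "satiation",
                 by: list[str] | None = None, response: str = "error_rate",
                 ) -> dict[tuple, FitResult]:
    """Fit the chosen model separately within each group of ``by`` columns.

    Default grouping is per subject x treatment.
    """
    if by is None:
        by = ["subject_id", "treatment"]
    fit = fit_satiation_model if model == "satiation" else fit_reward_size_model
    out: dict[tuple, FitResult] = {}
    for key, grp in table.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = fit(grp, response=response)
    return out
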