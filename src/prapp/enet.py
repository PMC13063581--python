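"""Elastic-net logistic regression with two-stage hyperparameter selection.

The model for PrEP use is a penalized logistic regression over the binary
indicator columns of the design matrix, minimizing

    (1/n) sum_i logloss_i + strength * (mixing * ||b||_1
                                        + (1 - mixing)/2 * ||b||_2^2)

(the glmnet parameterization; the intercept is unpenalized).  Note the field
literature sometimes swaps the two Greek letters for these hyperparameters,
so this package only ever calls them *mixing* (L1 share, in (0, 1]) and
*strength* (overall penalty weight).

Selection is two-stage:

1. For each mixing value on a fixed grid, repeated stratified k-fold
   cross-validation scores every strength by mean validation AUC, and the
   elbow is taken by the one-standard-error rule: the largest strength whose
   mean AUC is within one standard error of the best strength's mean AUC
   (largest = sparsest; ties prefer the larger strength).
2. One model per mixing is refitted on the full data at its selected
   strength, and the final model minimizes, lexicographically, the number of
   non-zero coefficients, then AIC, then (for determinism) prefers the
   larger mixing.

AIC uses k = n_nonzero + 1 effective parameters and the *unpenalized*
log-likelihood evaluated at the penalized estimates, the standard
degrees-of-freedom result for lasso-type fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .covariates import DesignMatrix

DEFAULT_MIXING_GRID = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
DEFAULT_STRENGTH_GRID = (1.0, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001)


class StratificationError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class TuningConfig:
    mixing_grid: tuple[float, ...] = DEFAULT_MIXING_GRID
    n_folds: int = 15
    n_repeats: int = 5
    strength_grid: tuple[float, ...] = DEFAULT_STRENGTH_GRID
    seed: int = 0
    max_iter: int = 5000
    tol: float = 1e-6

    def validate(self) -> None:
        if not all(0.0 < m <= 1.0 for m in self.mixing_grid):
            raise ValueError("mixing values must lie in (0, 1]")
        sg = list(self.strength_grid)
        if not all(s > 0 for s in sg) or sg != sorted(sg, reverse=True):
            raise ValueError("strength_grid must be positive and strictly decreasing")
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


@dataclass
class FittedModel:
    mixing: float
    strength: float
    intercept: float
    coef: pd.Series  # indexed by design-matrix column name
    n_nonzero: int
    log_likelihood: float
    aic: float

    def nonzero_coef(self) -> pd.Series:
        return self.coef[self.coef != 0.0]


def _estimator(mixing: float, strength: float, n: int, max_iter: int, tol: float):
    # sklearn scales the loss by C and leaves the penalty unit-weighted:
    # C = 1 / (n * strength) recovers the per-observation objective above.
    return LogisticRegression(
        solver="saga",
        l1_ratio=float(mixing),
        C=1.0 / (n * float(strength)),
        max_iter=max_iter,
        tol=tol,
        random_state=0,
    )


def _fit_raw(X: np.ndarray, y: np.ndarray, mixing, strength, max_iter, tol):
    est = _estimator(mixing, strength, len(y), max_iter, tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def _polish_intercept(b: float, offset: np.ndarray, y: np.ndarray) -> float:
    """Newton steps for the unpenalized intercept at fixed coefficients.

    The saga solver can stop after a single epoch once the penalty has
    zeroed every coefficient, leaving the intercept short of its optimum;
    given fixed coefficients the intercept solves a smooth 1-D problem, so
    it is polished to the exact conditional optimum here.
    """
    y_sum = float(np.sum(y))
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(b + offset)))
        hessian = float(np.sum(p * (1.0 - p)))
        if hessian <= 0.0:
            break
        step = (float(np.sum(p)) - y_sum) / hessian
        b -= step
        if abs(step) < 1e-12:
            break
    return float(b)


def cv_tune(matrix: DesignMatrix, config: TuningConfig) -> pd.DataFrame:
    """Cross-validated AUC surface over (mixing, strength).

    Returns one row per grid pair with ``mean_cv_auc``, ``sd_cv_auc`` (over
    folds x repeats), ``n_eval`` and the non-zero count of a full-data fit
    at that pair.
    """
    config.validate()
    y = matrix.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.n_folds:
        raise StratificationError(
            f"need >= {config.n_folds} members per outcome class, have {counts.tolist()}"
        )
    X = matrix.X.to_numpy(dtype=float)
    splitter = RepeatedStratifiedKFold(
        n_splits=config.n_folds, n_repeats=config.n_repeats, random_state=config.seed
    )
    splits = list(splitter.split(X, y))
    rows = []
    for mixing in config.mixing_grid:
        for strength in config.strength_grid:
            aucs = []
            for train, val in splits:
                if len(np.unique(y[val])) < 2:  # cannot happen with proper stratification
                    raise StratificationError("validation fold with a single outcome class")
                est = _fit_raw(X[train], y[train], mixing, strength, config.max_iter, config.tol)
                aucs.append(roc_auc_score(y[val], est.decision_function(X[val])))
            full = _fit_raw(X, y, mixing, strength, config.max_iter, config.tol)
            rows.append(
                {
                    "mixing": mixing,
                    "strength": strength,
                    "mean_cv_auc": float(np.mean(aucs)),
                    "sd_cv_auc": float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
                    "n_eval": len(aucs),
                    "n_nonzero": int(np.count_nonzero(full.coef_)),
                }
            )
    return pd.DataFrame(rows)


def select_strength(rows: pd.DataFrame) -> float:
    """One-SE elbow rule on the strength path of a single mixing value."""
    if rows.empty:
        raise ValueError("no tuning rows to select from")
    if rows["mixing"].nunique() > 1:
        raise ValueError("select_strength expects rows for a single mixing value")
    best = rows.loc[rows["mean_cv_auc"].idxmax()]
    n_eval = float(best.get("n_eval", 1) or 1)
    se = float(best["sd_cv_auc"]) / np.sqrt(n_eval)
    eligible = rows[rows["mean_cv_auc"] >= float(best["mean_cv_auc"]) - se]
    return float(eligible["strength"].max())


def fit_final(
    matrix: DesignMatrix,
    mixing: float,
    strength: float,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> FittedModel:
    """Full-data elastic-net fit at fixed hyperparameters."""
    if strength <= 0:
        raise ValueError("strength must be positive")
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y
    est = _fit_raw(X, y, mixing, strength, max_iter, tol)
    if int(np.max(est.n_iter_)) >= max_iter:
        raise ConvergenceError(
            f"no convergence within {max_iter} iterations at "
            f"(mixing={mixing}, strength={strength})"
        )
    coef = pd.Series(est.coef_.ravel(), index=list(matrix.X.columns))
    intercept = _polish_intercept(float(est.intercept_[0]), X @ coef.to_numpy(), y)
    eta = intercept + X @ coef.to_numpy()
    # unpenalized Bernoulli log-likelihood at the penalized estimates
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    nnz = int(np.count_nonzero(coef.to_numpy()))
    return FittedModel(
        mixing=float(mixing),
        strength=float(strength),
        intercept=intercept,
        coef=coef,
        n_nonzero=nnz,
        log_likelihood=ll,
        aic=2.0 * (nnz + 1) - 2.0 * ll,
    )


def choose_model(candidates: Sequence[FittedModel]) -> FittedModel:
    """Lexicographic choice: fewest non-zeros, then lowest AIC, then larger mixing."""
    if not candidates:
        raise ValueError("no candidate models")
    return min(candidates, key=lambda m: (m.n_nonzero, m.aic, -m.mixing))


def tune_and_select(
    matrix: DesignMatrix, config: TuningConfig
) -> tuple[pd.DataFrame, list[FittedModel], FittedModel]:
    """Run both selection stages; returns (tuning grid, per-mixing fits, chosen)."""
    grid = cv_tune(matrix, config)
    candidates = []
    for mixing in config.mixing_grid:
        rows = grid[grid["mixing"] == mixing]
        strength = select_strength(rows)
        candidates.append(
            fit_final(matrix, mixing, strength, config.max_iter, config.tol)
        )
    return grid, candidates, choose_model(candidates)
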