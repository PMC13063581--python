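"""Stratified bootstrap of the chosen elastic-net model.

Resampling is with replacement *within* each outcome class, so every
replicate keeps the original user / non-user balance.  The chosen model's
hyperparameters stay fixed across replicates (no re-tuning inside the
bootstrap).  Per coefficient the summary reports the full-data point
estimate, the percentile confidence interval (linear-interpolation
quantiles) and a one-sided bootstrap p-value

    p = (1 + #{replicates with opposite sign, or exactly zero}) / (B + 1),

with p = 1 when the point estimate itself is zero.  Replicates shrunk to
exactly zero count against significance: the penalty puts point mass at
zero, and treating that mass as non-support is the conservative reading.
The +1 smoothing keeps p away from zero at finite B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import DesignMatrix
from .enet import FittedModel, StratificationError, _fit_raw


@dataclass
class BootstrapConfig:
    n_samples: int = 10_000
    ci_level: float = 0.95
    seed: int = 0
    max_iter: int = 5000
    tol: float = 1e-6

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("need at least one bootstrap sample")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


def stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of one resample preserving each outcome class's size exactly."""
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise StratificationError("both outcome classes must be present")
    parts = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        parts.append(rng.choice(idx, size=len(idx), replace=True))
    return np.concatenate(parts)


def bootstrap_coefficients(
    matrix: DesignMatrix,
    mixing: float,
    strength: float,
    config: BootstrapConfig,
) -> pd.DataFrame:
    """Replicate-by-column coefficient table (B rows).

    Replicates that fail to converge are dropped and counted; more than 1%
    drops aborts the run.
    """
    config.validate()
    X = matrix.X.to_numpy(dtype=float)
    y = matrix.y
    rng = np.random.default_rng(config.seed)
    rows = []
    dropped = 0
    for _ in range(config.n_samples):
        idx = stratified_resample(y, rng)
        try:
            est = _fit_raw(X[idx], y[idx], mixing, strength, config.max_iter, config.tol)
        except Exception:
            dropped += 1
            continue
        if int(np.max(est.n_iter_)) >= config.max_iter:
            dropped += 1
            continue
        rows.append(est.coef_.ravel())
    if dropped > 0.01 * config.n_samples:
        raise RuntimeError(
            f"{dropped}/{config.n_samples} bootstrap replicates failed to converge"
        )
    return pd.DataFrame(np.asarray(rows), columns=list(matrix.X.columns))


def percentile_ci(replicates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tail empirical quantiles with linear interpolation."""
    replicates = np.asarray(replicates, dtype=float)
    if replicates.size < 2:
        raise ValueError("need at least two replicates for a percentile interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(replicates, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def bootstrap_p(replicates: np.ndarray, point_estimate: float) -> float:
    """One-sided bootstrap p-value; see module docstring for the convention."""
    replicates = np.asarray(replicates, dtype=float)
    b = replicates.size
    if point_estimate == 0.0:
        return 1.0
    if point_estimate > 0:
        against = np.count_nonzero(replicates <= 0.0)
    else:
        against = np.count_nonzero(replicates >= 0.0)
    return (1 + against) / (b + 1)


def summarize(
    replicates: pd.DataFrame, model: FittedModel, ci_level: float = 0.95
) -> pd.DataFrame:
    """Per-column bootstrap summary keyed to the chosen model's columns."""
    rows = []
    for col in replicates.columns:
        vals = replicates[col].to_numpy()
        point = float(model.coef[col])
        lo, hi = percentile_ci(vals, ci_level)
        rows.append(
            {
                "column": col,
                "beta": point,
                "ci_low": lo,
                "ci_high": hi,
                "p_one_sided": bootstrap_p(vals, point),
                "zero_fraction": float(np.mean(vals == 0.0)),
            }
        )
    return pd.DataFrame(rows).set_index("column")
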