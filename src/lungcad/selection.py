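"""PLSR feature reduction.

The 1056-column feature matrix X and 0/1 label vector y enter the linear
model y = X b + e.  Partial least squares extracts latent factors that
maximize covariance between X and y; the factor count is the smallest k
whose cumulative fraction of response variance explained reaches a
threshold (default 0.90).  Downstream classifiers consume the k-column
factor-score matrix, never the raw 1056 columns.  Columns are
mean-centered but not variance-scaled: histogram-bin features already
share a unit-mass scale.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger("lungcad")

DEFAULT_VARIANCE_THRESHOLD = 0.90


@dataclasses.dataclass
class PLSRModel:
    """Fitted PLS regression with per-factor response-variance accounting."""

    n_factors: int
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    cum_var_y: np.ndarray
    _pls: PLSRegression = dataclasses.field(repr=False, default=None)
    _train_scores: np.ndarray = dataclasses.field(repr=False, default=None)


def plsr_fit(X: np.ndarray, y: np.ndarray, max_factors: int | None = None) -> PLSRModel:
    """Fit PLS factors and the cumulative response variance they explain.

    ``max_factors`` defaults to min(n - 1, p, 20).  The x-scores of
    sequential PLS are mutually orthogonal, so the variance of y explained
    by the first k factors accumulates as sum_j (t_j . y_c)^2 / |t_j|^2
    over the centered response y_c -- guaranteeing a non-decreasing
    ``cum_var_y``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if np.unique(y).size < 2:
        raise ValueError("response must contain both classes")
    limit = min(n - 1, p)
    if max_factors is None:
        max_factors = min(limit, 20)
    if not 1 <= max_factors <= limit:
        raise ValueError(f"max_factors must be in [1, {limit}]")

    pls = PLSRegression(n_components=max_factors, scale=False)
    pls.fit(X, y)

    yc = y - y.mean()
    ss_total = float(yc @ yc)
    T = pls.x_scores_
    contrib = np.array([(t @ yc) ** 2 / max(t @ t, 1e-300) for t in T.T])
    cum_var_y = np.minimum(np.cumsum(contrib) / ss_total, 1.0)

    return PLSRModel(
        n_factors=max_factors,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        y_loadings=pls.y_loadings_.ravel(),
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        cum_var_y=cum_var_y,
        _pls=pls,
        _train_scores=T,
    )


def select_n_factors(model: PLSRModel, threshold: float = DEFAULT_VARIANCE_THRESHOLD) -> int:
    """Smallest factor count reaching ``threshold`` cumulative response variance.

    Falls back to the fitted maximum (with a logged warning) when the
    threshold is never reached.
    """
    reached = np.flatnonzero(model.cum_var_y >= threshold)
    if reached.size:
        return int(reached[0]) + 1
    logger.warning(
        "PLSR cumulative response variance tops out at %.3f < %.2f; using all %d factors",
        model.cum_var_y[-1],
        threshold,
        model.n_factors,
    )
    return model.n_factors


def transform(model: PLSRModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Project (centered) new rows onto the first ``n_factors`` factor directions."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model was trained with {model.x_mean.shape[0]}"
        )
    k = model.n_factors if n_factors is None else int(n_factors)
    if not 1 <= k <= model.n_factors:
        raise ValueError(f"n_factors must be in [1, {model.n_factors}]")
    return model._pls.transform(X_new)[:, :k]
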