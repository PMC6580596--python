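"""Vectorized rank-correlation helpers shared by the screening and model code.

Per-probe Spearman statistics are computed as Pearson correlations on
column ranks, with p-values from the t approximation (df = n - 2), which
is what the rest of the package assumes throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def rank_transform(X: np.ndarray) -> np.ndarray:
    """Column-wise midranks of a 2-D array (ties get average rank)."""
    return stats.rankdata(np.asarray(X, dtype=float), axis=0)


def standardized_ranks(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scored ranks; constant columns become all-zero.

    With both arguments z-scored, ``z_a @ z_b / n`` is the Spearman
    correlation of the underlying columns.
    """
    R = rank_transform(X)
    R = R - R.mean(axis=0, keepdims=True)
    sd = R.std(axis=0, ddof=0)
    nz = sd > 0
    R[:, nz] /= sd[nz]
    R[:, ~nz] = 0.0
    return R


def spearman_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each column of X against y.

    Constant columns yield NaN; constant y raises ValueError.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError(f"shape mismatch: X has {X.shape[0]} rows, y has {n}")
    ry = rank_transform(y[:, None]).ravel()
    sy = ry.std(ddof=0)
    if sy == 0:
        raise ValueError("y is constant; Spearman correlation undefined")
    zy = (ry - ry.mean()) / sy
    Z = standardized_ranks(X)
    rho = Z.T @ zy / n
    sd = rank_transform(X).std(axis=0, ddof=0)
    rho[sd == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Spearman rho via the t approximation.

    NaN rho (constant probe) maps to p = 1 so that such probes are never
    selected by a significance screen.
    """
    rho = np.asarray(rho, dtype=float)
    if n < 3:
        raise ValueError("need at least 3 observations for a p-value")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), 1.0, p)
    # |rho| == 1 gives t = inf -> sf = 0
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and t-approximation p for a single pair of vectors."""
    rho = spearman_vector(np.asarray(x, dtype=float)[:, None], y)[0]
    if np.isnan(rho):
        return float("nan"), float("nan")
    p = spearman_pvalues(np.array([rho]), len(np.asarray(y).ravel()))[0]
    return float(rho), float(p)
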