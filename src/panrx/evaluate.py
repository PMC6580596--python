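"""Scoring of held-out predictions: Spearman, MAD, and the wpc-index.

The weighted-probability concordance index scores pairwise ranking
agreement, down-weighting measured pairs whose ordering could plausibly
be replicate noise: w_ij = Phi(|dy_ij| / (noise_sd * sqrt(2))). It is 0.5
in expectation under random permutation of the predictions and is
undefined (a raised error, never a silent NaN) when the predictions have
zero variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import PredictionSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "NullDistribution",
    "WpcUndefinedError",
    "spearman_eval",
    "mad_eval",
    "wpc_index",
    "wpc_null_test",
    "paired_method_comparison",
    "evaluate_predictions",
]


class WpcUndefinedError(ValueError):
    """Raised when the wpc-index is undefined (zero prediction variance)."""


@dataclass
class EvalResult:
    spearman_rho: float
    spearman_p: float
    mad: float
    wpc: float | None
    n_test: int


@dataclass
class NullDistribution:
    """Permutation null for one statistic with the +1-corrected empirical p."""

    values: np.ndarray
    observed: float
    p: float


def spearman_eval(pred: PredictionSet) -> tuple[float, float]:
    """Spearman rho and t-approximation p between predicted and measured.

    Constant predictions give (nan, nan) with a log record rather than a
    silent zero.
    """
    if len(pred) < 5:
        raise ValueError(f"need >= 5 test cells, got {len(pred)}")
    ym, yp = pred.y_measured, pred.y_predicted
    if np.all(ym == ym[0]):
        raise ValueError("measured values all tied; correlation undefined")
    if np.all(yp == yp[0]):
        logger.warning("constant predictions; Spearman undefined for this set")
        return float("nan"), float("nan")
    n = len(ym)
    rho = stats.spearmanr(yp, ym).statistic
    t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def mad_eval(pred: PredictionSet) -> float:
    """Mean absolute difference between predicted and measured (log IC50)."""
    if len(pred) < 1:
        raise ValueError("empty prediction set")
    return float(np.mean(np.abs(pred.y_predicted - pred.y_measured)))


def _wpc_from_arrays(ym: np.ndarray, yp: np.ndarray, noise_sd: float) -> float:
    n = len(ym)
    iu, ju = np.triu_indices(n, k=1)
    dm = ym[iu] - ym[ju]
    dp = yp[iu] - yp[ju]
    keep = dm != 0  # tied measured pairs carry no ordering information
    dm, dp = dm[keep], dp[keep]
    if len(dm) == 0:
        raise WpcUndefinedError("no measured pairs with distinct values")
    if noise_sd > 0:
        w = stats.norm.cdf(np.abs(dm) / (noise_sd * np.sqrt(2.0)))
    else:
        w = np.ones_like(dm)
    c = np.where(dp == 0, 0.5, (np.sign(dp) == np.sign(dm)).astype(float))
    return float(np.sum(w * c) / np.sum(w))


def wpc_index(pred: PredictionSet, noise_sd: float = 0.0) -> float:
    """Weighted-probability concordance of predicted vs measured ordering.

    Pairs are weighted by the probability that the measured ordering is
    real under a Gaussian replicate-noise model of scale ``noise_sd``
    (``noise_sd = 0`` weights all pairs equally). Predicted ties score
    0.5. Zero prediction variance raises WpcUndefinedError.
    """
    if len(pred) < 2:
        raise ValueError("need >= 2 test cells")
    yp = pred.y_predicted
    if np.var(yp) == 0:
        raise WpcUndefinedError(
            "predictions have zero variance; wpc-index undefined (division by zero)"
        )
    return _wpc_from_arrays(pred.y_measured, yp, noise_sd)


def estimate_noise_sd(measurements=None, response_sd: float | None = None, frac: float = 0.1) -> float:
    """Replicate-noise scale: median within-cell SD, else a fraction of the response SD."""
    if measurements is not None:
        sds = measurements.groupby("cell_id")["log_ic50"].std(ddof=1).dropna()
        if len(sds):
            return float(sds.median())
    if response_sd is None:
        raise ValueError("need replicate measurements or a response SD")
    return float(frac * response_sd)


def wpc_null_test(
    pred: PredictionSet, noise_sd: float = 0.0, n_perm: int = 3000, seed: int = 0
) -> NullDistribution:
    """Permutation null of the wpc-index; one-sided +1-corrected p."""
    observed = wpc_index(pred, noise_sd)
    rng = np.random.default_rng(seed)
    ym, yp = pred.y_measured, pred.y_predicted
    values = np.empty(n_perm)
    for i in range(n_perm):
        values[i] = _wpc_from_arrays(ym, yp[rng.permutation(len(yp))], noise_sd)
    p = (1.0 + np.sum(values >= observed)) / (n_perm + 1.0)
    return NullDistribution(values, observed, float(p))


@dataclass
class ComparisonResult:
    statistic: float
    p: float
    n_used: int
    all_tied: bool


def paired_method_comparison(scores_a, scores_b) -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired scores; zeros dropped."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired score vectors must have equal length")
    if len(a) < 5:
        raise ValueError("need >= 5 paired datasets")
    diff = a - b
    nonzero = diff != 0
    if not nonzero.any():
        return ComparisonResult(float("nan"), 1.0, 0, all_tied=True)
    res = stats.wilcoxon(a[nonzero], b[nonzero], zero_method="wilcox", mode="auto")
    return ComparisonResult(float(res.statistic), float(res.pvalue), int(nonzero.sum()), False)


def evaluate_predictions(
    pred: PredictionSet, noise_sd: float | None = None
) -> EvalResult:
    """All three metrics for one prediction set; wpc is None when undefined."""
    rho, p = spearman_eval(pred)
    mad = mad_eval(pred)
    try:
        wpc = wpc_index(pred, noise_sd if noise_sd is not None else 0.0)
    except WpcUndefinedError:
        logger.warning("wpc undefined for %s/%s", pred.family, pred.feature_method)
        wpc = None
    return EvalResult(rho, p, mad, wpc, len(pred))
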