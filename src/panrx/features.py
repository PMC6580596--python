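"""Correlation-based feature selection, its controls, and histotype encoding.

All selectors operate on training cells only. Methods:

- NOFS      every probe
- DEG       Spearman screen at p < alpha
- BC        Spearman screen at the Bonferroni-corrected cutoff alpha / m
- MODT      empirical-Bayes moderated t on response-tail groups, BH-FDR cut
- BS        probe significant in all of n_boot random 75% subsets
- BS_HIST   probe significant in >= half of one-cell-per-histotype subsets
- MRMR      greedy max-relevance / min-redundancy on Spearman correlations
- CTR1      size-matched uniform random probe set
- CTR2      complement of the DEG set
- RCTR      size-matched probes with each column shuffled across cells
- HIST      one-hot histotype encoding in place of expression
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from ._stats import spearman_pvalues, spearman_vector, standardized_ranks
from .cohort import HistotypeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "ScreenResult",
    "spearman_screen",
    "bonferroni_threshold",
    "select_moderated_t",
    "select_bootstrap",
    "select_mrmr",
    "make_control_features",
    "shuffle_matrix",
    "encode_histotype",
]

METHODS = ("NOFS", "DEG", "MODT", "BC", "BS", "BS_HIST", "MRMR", "CTR1", "CTR2", "RCTR", "HIST")


@dataclass
class FeatureSet:
    """An ordered probe subset plus the method and parameters that made it."""

    method: str
    probe_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in feature set")

    @property
    def n_features(self) -> int:
        return len(self.probe_ids)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"method": self.method, "params": self.params, "probe_ids": self.probe_ids},
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "FeatureSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["method"], d["probe_ids"], d.get("params", {}))


@dataclass
class ScreenResult:
    """Per-probe Spearman rho and p against response, training cells only."""

    table: pd.DataFrame  # columns: rho, p; index: probe ids

    @property
    def rho(self) -> pd.Series:
        return self.table["rho"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


def _check_training(X: pd.DataFrame, y: pd.Series, min_cells: int = 5) -> np.ndarray:
    if len(X) != len(y):
        raise ValueError("X and y have different numbers of cells")
    if len(y) < min_cells:
        raise ValueError(f"need at least {min_cells} training cells, got {len(y)}")
    yv = np.asarray(y, dtype=float)
    if np.all(yv == yv[0]):
        raise ValueError("constant response; screen undefined")
    return yv


def spearman_screen(
    X_train: pd.DataFrame, y_train: pd.Series, alpha: float = 0.05, method: str = "DEG"
) -> tuple[ScreenResult, FeatureSet]:
    """Select probes with Spearman p < alpha against the training response.

    Constant probes are assigned p = 1 (logged), never selected.
    """
    yv = _check_training(X_train, y_train)
    rho = spearman_vector(X_train.to_numpy(dtype=float), yv)
    n_const = int(np.isnan(rho).sum())
    if n_const:
        logger.info("%d constant probes assigned p=1 in screen", n_const)
    p = spearman_pvalues(rho, len(yv))
    table = pd.DataFrame({"rho": rho, "p": p}, index=X_train.columns)
    selected = [str(pid) for pid in X_train.columns[p < alpha]]
    fs = FeatureSet(method, selected, {"alpha": alpha})
    return ScreenResult(table), fs


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test cutoff alpha / m."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / m


def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log sample variances.

    Models s2 ~ s0^2 * F(df, d0); uses the mean/variance of
    log(s2) corrected by digamma/trigamma terms. Returns
    (d0, s0sq); d0 = inf when the observed spread is below the
    chi-square floor.
    """
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        raise ValueError("need >= 2 positive sample variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar)[0])
        s0sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0sq = float(np.exp(e.mean()))
    return d0, s0sq


def moderated_t_statistics(
    X_high: np.ndarray, X_low: np.ndarray, d0_override: float | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-probe moderated two-sample t between two cell groups.

    The pooled sample variance is shrunk toward a prior estimated by
    moment matching: s~^2 = (d0*s0^2 + d*s^2) / (d0 + d); the statistic is
    referred to a t distribution with d + d0 degrees of freedom.
    ``d0_override = 0`` reduces exactly to the ordinary pooled t.
    Returns (t, p, d0).
    """
    n1, n2 = X_high.shape[0], X_low.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 cells")
    d = n1 + n2 - 2
    m1, m2 = X_high.mean(axis=0), X_low.mean(axis=0)
    ss = X_high.var(axis=0, ddof=1) * (n1 - 1) + X_low.var(axis=0, ddof=1) * (n2 - 1)
    s2 = ss / d
    if np.all(s2 == 0):
        raise ValueError("zero within-group variance for every probe")
    if d0_override is not None:
        d0 = float(d0_override)
        s0sq = 0.0 if d0 == 0 else _fit_variance_prior(s2, d)[1]
    else:
        d0, s0sq = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = 1e6  # effectively normal
    else:
        s2_tilde = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d + d0
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    from scipy import stats as _st

    p = 2.0 * _st.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isnan(t), 1.0, p)
    return t, p, d0


def select_moderated_t(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    tail_frac: float = 0.25,
    fdr: float = 0.05,
    d0_override: float | None = None,
) -> FeatureSet:
    """Empirical-Bayes moderated t between response tails, BH cut at q = fdr.

    The resistant group is the top ``tail_frac`` of cells by response and
    the sensitive group the bottom ``tail_frac``.
    """
    yv = _check_training(X_train, y_train, min_cells=6)
    n = len(yv)
    k = int(np.floor(tail_frac * n))
    if k < 3:
        raise ValueError(f"tail of {k} cells too small (need >= 3)")
    order = np.argsort(yv, kind="stable")
    low_idx, high_idx = order[:k], order[-k:]
    Xv = X_train.to_numpy(dtype=float)
    t, p, d0 = moderated_t_statistics(Xv[high_idx], Xv[low_idx], d0_override)
    reject, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    selected = [str(pid) for pid in X_train.columns[reject]]
    return FeatureSet(
        "MODT", selected, {"tail_frac": tail_frac, "fdr": fdr, "d0": float(d0)}
    )


def select_bootstrap(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    n_boot: int = 50,
    subset_frac: float = 0.75,
    alpha: float = 0.05,
    consensus: float = 1.0,
    stratify_histotype: bool = False,
    annotation: HistotypeAnnotation | None = None,
    seed: int = 0,
) -> FeatureSet:
    """Keep probes significant in enough random training subsets.

    Plain mode (BS): each subset is a random ``subset_frac`` of the
    training cells and a probe must pass in a ``consensus`` fraction of
    subsets (default all of them). Histotype mode (BS_HIST): each subset
    holds one randomly chosen cell per histotype and the default consensus
    is half the subsets.
    """
    if not (0.0 < consensus <= 1.0):
        raise ValueError(f"consensus must be in (0, 1], got {consensus}")
    yv = _check_training(X_train, y_train)
    if stratify_histotype and annotation is None:
        raise ValueError("histotype mode needs an annotation")
    rng = np.random.default_rng(seed)
    n = len(yv)
    Xv = X_train.to_numpy(dtype=float)
    hits = np.zeros(Xv.shape[1], dtype=int)
    cells = list(X_train.index.astype(str))
    if stratify_histotype:
        labels = annotation.subset(cells).labels
        groups = [np.flatnonzero(labels.values == h) for h in sorted(labels.unique())]
    for _ in range(n_boot):
        if stratify_histotype:
            idx = np.array([g[rng.integers(len(g))] for g in groups])
        else:
            size = max(int(round(subset_frac * n)), 5)
            idx = rng.choice(n, size=min(size, n), replace=False)
        if len(idx) < 5:
            raise ValueError("bootstrap subsets too small for the screen (< 5 cells)")
        ys = yv[idx]
        if np.all(ys == ys[0]):
            continue  # degenerate subset contributes no hits
        rho = spearman_vector(Xv[idx], ys)
        p = spearman_pvalues(rho, len(idx))
        hits += (p < alpha).astype(int)
    need = int(np.ceil(consensus * n_boot))
    selected = [str(pid) for pid in X_train.columns[hits >= need]]
    method = "BS_HIST" if stratify_histotype else "BS"
    return FeatureSet(
        method,
        selected,
        {"n_boot": n_boot, "alpha": alpha, "consensus": consensus, "seed": seed},
    )


def select_mrmr(X_train: pd.DataFrame, y_train: pd.Series, k: int = 1000) -> FeatureSet:
    """Greedy max-relevance min-redundancy selection on Spearman correlations.

    The first probe maximizes |rho(x, y)|; each later pick maximizes
    |rho(x, y)| - mean_{s in S} |rho(x, x_s)|. Ties break to the lowest
    probe index, so the result is deterministic.
    """
    yv = _check_training(X_train, y_train)
    m = X_train.shape[1]
    if k > m:
        raise ValueError(f"k={k} exceeds {m} available probes")
    n = len(yv)
    Z = standardized_ranks(X_train.to_numpy(dtype=float))
    zy = standardized_ranks(yv[:, None]).ravel()
    relevance = np.abs(Z.T @ zy / n)

    chosen: list[int] = []
    red_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for _ in range(k):
        if chosen:
            score = relevance - red_sum / len(chosen)
        else:
            score = relevance.copy()
        score[~available] = -np.inf
        g = int(np.argmax(score))  # first max wins ties -> lowest index
        chosen.append(g)
        available[g] = False
        red_sum += np.abs(Z.T @ Z[:, g] / n)
    probes = [str(X_train.columns[g]) for g in chosen]
    return FeatureSet("MRMR", probes, {"k": k})


def make_control_features(
    all_probes, reference: FeatureSet, mode: str, seed: int = 0
) -> FeatureSet:
    """Size-matched random control (CTR1) or DEG-complement control (CTR2)."""
    all_probes = [str(p) for p in all_probes]
    ref = set(reference.probe_ids)
    assert len(ref) <= len(all_probes), "reference larger than probe universe"
    if mode == "CTR1":
        rng = np.random.default_rng(seed)
        picked = list(rng.choice(all_probes, size=len(ref), replace=False))
        return FeatureSet("CTR1", picked, {"seed": seed, "n": len(ref)})
    if mode == "CTR2":
        picked = [p for p in all_probes if p not in ref]
        return FeatureSet("CTR2", picked, {"reference_n": len(ref)})
    raise ValueError(f"mode must be CTR1 or CTR2, got {mode!r}")


def shuffle_matrix(
    X: pd.DataFrame, n_features: int, seed: int = 0
) -> tuple[pd.DataFrame, FeatureSet]:
    """Sample n_features probes and permute each column across cells (RCTR).

    The response is untouched by construction; the returned matrix keeps
    the original cell index and the sampled probe names.
    """
    if n_features > X.shape[1]:
        raise ValueError(f"n_features={n_features} exceeds {X.shape[1]} probes")
    rng = np.random.default_rng(seed)
    cols = list(rng.choice(X.columns.astype(str), size=n_features, replace=False))
    vals = X[cols].to_numpy(dtype=float).copy()
    for j in range(vals.shape[1]):
        vals[:, j] = vals[rng.permutation(vals.shape[0]), j]
    shuffled = pd.DataFrame(vals, index=X.index, columns=cols)
    return shuffled, FeatureSet("RCTR", cols, {"seed": seed, "n": n_features})


def encode_histotype(annotation: HistotypeAnnotation, cells) -> pd.DataFrame:
    """One-hot histotype matrix for the given cells, columns = sorted labels."""
    cells = [str(c) for c in cells]
    sub = annotation.subset(cells)  # raises on unlabeled cells
    labels = sorted(sub.labels.unique())
    onehot = pd.DataFrame(0, index=cells, columns=labels, dtype=float)
    for c in cells:
        onehot.loc[c, sub.label_of(c)] = 1.0
    return onehot
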