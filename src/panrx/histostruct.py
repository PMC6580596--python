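"""How strongly features encode histotype, and histotype encodes response.

Two diagnostics: (1) k-means clustering of cells on a feature subset,
summarized by cluster entropy S_c — the cluster-size-weighted mean of the
within-cluster histotype-label entropy, 0 when every cluster is pure —
reported normalized by the S_c of a matched shuffled-matrix control; and
(2) pairwise two-group F-tests of response between histotypes, summarized
by the fraction of significant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._stats import spearman_rho_p
from .cohort import HistotypeAnnotation
from .features import shuffle_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "FTestMatrix",
    "cluster_features",
    "cluster_entropy",
    "normalized_entropy",
    "pairwise_histotype_ftests",
    "histotype_signal_correlation",
]


@dataclass
class ClusteringResult:
    assignments: pd.Series  # cluster label per cell
    k: int
    inertia: float
    restart_inertias: list[float] = field(default_factory=list)
    S_c_raw: float | None = None
    S_c_normalized: float | None = None
    seed: int = 0


@dataclass
class FTestMatrix:
    """Pairwise histotype F statistics; symmetric, diagonal excluded."""

    table: pd.DataFrame  # columns: hist_a, hist_b, F, p
    fraction_significant: float
    alpha: float = 0.05


def cluster_features(
    X: pd.DataFrame,
    feature_set,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> ClusteringResult:
    """k-means on the selected probes, best of n_restarts by inertia.

    ``feature_set`` may be a FeatureSet or a plain list of probe ids; None
    uses every column.
    """
    if feature_set is None:
        cols = list(X.columns)
    else:
        cols = list(getattr(feature_set, "probe_ids", feature_set))
    if len(cols) < 1:
        raise ValueError("need at least one feature to cluster")
    if k > len(X):
        raise ValueError(f"k={k} exceeds {len(X)} cells")
    V = X[cols].to_numpy(dtype=float)
    streams = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    inertias = []
    for st in streams:
        child_seed = int(st.generate_state(1)[0] % (2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=child_seed)
        km.fit(V)
        inertias.append(float(km.inertia_))
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assignments = pd.Series(best.labels_, index=X.index, name="cluster")
    return ClusteringResult(assignments, k, float(best.inertia_), inertias, seed=seed)


def cluster_entropy(assignments: pd.Series, annotation: HistotypeAnnotation | pd.Series) -> float:
    """S_c = sum_j (n_j / N) * H_j, H_j the natural-log histotype entropy of cluster j.

    0 iff every (non-empty) cluster contains a single histotype.
    """
    labels = annotation.labels if isinstance(annotation, HistotypeAnnotation) else pd.Series(annotation)
    labels = labels.loc[assignments.index]
    N = len(assignments)
    if N == 0:
        raise ValueError("empty assignment vector")
    s_c = 0.0
    for _, members in labels.groupby(assignments.values):
        p = members.value_counts(normalize=True).to_numpy()
        h_j = float(-(p * np.log(p)).sum())
        s_c += (len(members) / N) * h_j
    return s_c


def normalized_entropy(
    S_c_raw: float,
    X: pd.DataFrame,
    annotation: HistotypeAnnotation,
    feature_count: int,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    n_random: int = 5,
    control_values: list[float] | None = None,
) -> tuple[float, list[float]]:
    """S_c divided by the mean S_c of matched shuffled-matrix controls.

    Controls are built by sampling ``feature_count`` probes and permuting
    each column across cells, clustered with the same parameters. Values
    above 1 are possible. A zero-mean control (pathological tiny data)
    raises rather than dividing by zero. Pass ``control_values`` to reuse
    draws (normalizing a control against its own draws gives exactly 1).
    """
    if control_values is None:
        control_values = []
        streams = np.random.SeedSequence((seed, 0xC0)).spawn(n_random)
        for st in streams:
            sub_seed = int(st.generate_state(1)[0] % (2**31 - 1))
            shuffled, _ = shuffle_matrix(X, feature_count, seed=sub_seed)
            res = cluster_features(shuffled, None, k, n_restarts=n_restarts, seed=sub_seed)
            control_values.append(cluster_entropy(res.assignments, annotation))
    denom = float(np.mean(control_values))
    if denom == 0:
        raise ValueError("random-control S_c is zero; normalized entropy undefined")
    return float(S_c_raw / denom), list(control_values)


def pairwise_histotype_ftests(
    response,
    annotation: HistotypeAnnotation | pd.Series,
    alpha: float = 0.05,
    min_cells: int = 3,
    welch: bool = False,
) -> FTestMatrix:
    """Two-group one-way ANOVA F for every histotype pair (F = t^2 pooled).

    Pairs where either group has fewer than ``min_cells`` cells are
    skipped and logged. ``welch=True`` swaps in the unequal-variance t.
    """
    labels = annotation.labels if isinstance(annotation, HistotypeAnnotation) else pd.Series(annotation)
    y = pd.Series(np.asarray(response, dtype=float), index=labels.index)
    groups = {h: y[labels == h].to_numpy() for h in sorted(labels.unique())}
    eligible = [h for h, v in groups.items() if len(v) >= min_cells]
    skipped = sorted(set(groups) - set(eligible))
    if skipped:
        logger.info("histotypes below %d cells skipped in F-tests: %s", min_cells, skipped[:5])
    if len(eligible) < 2:
        raise ValueError("need >= 2 histotypes with enough cells")
    rows = []
    for i, ha in enumerate(eligible):
        for hb in eligible[i + 1 :]:
            a, b = groups[ha], groups[hb]
            if welch:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                F = t**2
            else:
                n1, n2 = len(a), len(b)
                df = n1 + n2 - 2
                sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
                if sp2 == 0:
                    F, p = (np.inf, 0.0) if a.mean() != b.mean() else (0.0, 1.0)
                else:
                    F = (a.mean() - b.mean()) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
                    p = float(stats.f.sf(F, 1, df))
            rows.append({"hist_a": ha, "hist_b": hb, "F": float(F), "p": float(p)})
    table = pd.DataFrame(rows)
    frac = float((table["p"] < alpha).mean())
    return FTestMatrix(table, frac, alpha)


def histotype_signal_correlation(fraction_significant, model_rho) -> tuple[float, float]:
    """Spearman rho between per-drug F-test fractions and per-drug model rho."""
    a = np.asarray(fraction_significant, dtype=float)
    b = np.asarray(model_rho, dtype=float)
    if len(a) != len(b):
        raise ValueError("vectors must be paired per drug")
    if len(a) < 5:
        raise ValueError("need >= 5 drugs")
    if np.all(a == a[0]) or np.all(b == b[0]):
        logger.warning("constant vector; histotype-signal correlation undefined")
        return float("nan"), float("nan")
    return spearman_rho_p(a, b)
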