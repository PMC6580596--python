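"""Regression families, Monte Carlo CV tuning, and held-out prediction.

Families: principal-components regression (PCR), epsilon-insensitive
support vector regression with linear or RBF kernels, a single-hidden-
layer neural net with dropout (optional backend, implemented in numpy),
and a histotype-mean baseline (least squares on the one-hot encoding).

All hyperparameters are chosen by repeated random train/validation
subsampling on the training cells only; standardization statistics are
likewise learned on training cells only. Prediction aligns test columns
to the training feature list by name and never refits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .cohort import HistotypeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "PredictionSet",
    "monte_carlo_cv",
    "fit_pcr",
    "fit_svr",
    "fit_ann",
    "fit_histotype_mean",
    "predict",
    "make_prediction_set",
    "default_grid",
]

FAMILIES = ("PCR", "SVR_LINEAR", "SVR_RBF", "ANN", "HIST_MEAN")


def default_grid(family: str) -> list[dict]:
    """Default grids: 210 RBF combos, 30 linear combos, 4 dropout rates.

    The exact grid values are a package choice; they are ordered so that
    the Monte Carlo CV tie-break (first minimum wins) prefers the more
    regularized candidate.
    """
    if family == "SVR_RBF":
        Cs = np.logspace(-2, 3, 7)
        eps = (0.5, 0.1, 0.01)
        gammas = np.logspace(-4, 1, 10)
        return [
            {"C": float(c), "epsilon": float(e), "gamma": float(g)}
            for c in Cs
            for e in eps
            for g in gammas
        ]
    if family == "SVR_LINEAR":
        Cs = np.logspace(-2, 3, 10)
        eps = (0.5, 0.1, 0.01)
        return [{"C": float(c), "epsilon": float(e)} for c in Cs for e in eps]
    if family == "ANN":
        return [{"dropout": d} for d in (0.5, 0.25, 0.10, 0.0)]
    raise ValueError(f"no default grid for family {family!r}")


@dataclass
class ModelConfig:
    """Tuning configuration for one model family."""

    family: str
    grid: list[dict] | None = None
    cv_folds: int = 10
    cv_val_frac: float = 0.25
    seed: int = 0
    max_components: int = 30  # PCR candidate ceiling
    standardize: bool = True  # z-score features (SVR/ANN); PCR centers only
    ann_hidden: int = 20
    ann_epochs: int = 300
    ann_lr: float = 0.01

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.grid is not None and len(self.grid) == 0:
            raise ValueError("grid must be non-empty")
        if self.grid is not None and self.family in ("SVR_LINEAR", "SVR_RBF"):
            for g in self.grid:
                if g.get("C", 1.0) <= 0 or g.get("gamma", 1.0) <= 0:
                    raise ValueError(f"non-positive C or gamma in grid entry {g}")

    def resolved_grid(self) -> list[dict]:
        if self.grid is not None:
            return self.grid
        return default_grid(self.family)


@dataclass
class PredictionSet:
    """Paired measured/predicted responses on a held-out test set."""

    cell_ids: list[str]
    y_measured: np.ndarray
    y_predicted: np.ndarray
    drug: str = "drug"
    split_index: int = 0
    family: str = ""
    feature_method: str = ""

    def __post_init__(self) -> None:
        self.y_measured = np.asarray(self.y_measured, dtype=float)
        self.y_predicted = np.asarray(self.y_predicted, dtype=float)
        if not (len(self.cell_ids) == len(self.y_measured) == len(self.y_predicted)):
            raise ValueError("prediction set columns have unequal lengths")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "y_measured": self.y_measured,
                "y_predicted": self.y_predicted,
                "drug": self.drug,
                "split": self.split_index,
                "family": self.family,
                "feature_method": self.feature_method,
            }
        )


def _mc_folds(n: int, k: int, val_frac: float, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    n_val = int(round(val_frac * n))
    if n_val < 1:
        n_val = 1
    if n - n_val < 2:
        raise ValueError(f"training set of {n} too small for val_frac={val_frac}")
    rng = np.random.default_rng(seed)
    folds = []
    for _ in range(k):
        perm = rng.permutation(n)
        folds.append((perm[n_val:], perm[:n_val]))
    return folds


def monte_carlo_cv(
    candidates: list,
    X_train: np.ndarray,
    y_train: np.ndarray,
    fit_predict,
    k: int = 10,
    val_frac: float = 0.25,
    seed: int = 0,
):
    """Pick the candidate with lowest mean validation MSE over k random splits.

    The same k subsamples score every candidate. ``fit_predict(params,
    train_idx, val_idx, fold)`` must return validation predictions. Ties
    go to the earliest candidate, so callers order grids simple-first.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates")
    if len(candidates) == 1:
        return candidates[0]
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError(f"training set of {n} too small for Monte Carlo CV")
    folds = _mc_folds(n, k, val_frac, seed)
    losses = np.zeros(len(candidates))
    for fold, (tr, va) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            logger.warning("degenerate CV fold %d skipped (constant y)", fold)
            continue
        for ci, params in enumerate(candidates):
            pred = fit_predict(params, tr, va, fold)
            losses[ci] += np.mean((np.asarray(pred) - y[va]) ** 2)
    return candidates[int(np.argmin(losses))]


def _align(X_test, feature_names: list[str]) -> np.ndarray:
    """Name-based column alignment; a missing feature is a hard error."""
    if isinstance(X_test, pd.DataFrame):
        missing = [f for f in feature_names if f not in X_test.columns]
        if missing:
            raise KeyError(f"test matrix lacks trained feature(s): {missing[:5]}")
        return X_test[feature_names].to_numpy(dtype=float)
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != len(feature_names):
        raise KeyError("unnamed test matrix width differs from training features")
    return X


class PCRModel:
    """OLS on the top principal components of the centered training matrix."""

    family = "PCR"

    def __init__(self, feature_names, mean, components, coef, intercept, n_components):
        self.feature_names = list(feature_names)
        self.mean_ = mean
        self.components_ = components  # p x c
        self.coef_ = coef
        self.intercept_ = intercept
        self.n_components = n_components
        self.chosen_params = {"n_components": n_components}

    def predict(self, X_test) -> np.ndarray:
        X = _align(X_test, self.feature_names)
        scores = (X - self.mean_) @ self.components_
        return scores @ self.coef_ + self.intercept_


def _pcr_solve(Xc: np.ndarray, y: np.ndarray, c: int):
    """Fit component-space OLS via thin SVD; returns (V_c, coef, intercept)."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
    c = min(c, rank)
    yc = y - y.mean()
    coef = (U[:, :c].T @ yc) / s[:c]
    return Vt[:c].T, coef, float(y.mean())


def fit_pcr(X_train: pd.DataFrame, y_train, config: ModelConfig | None = None) -> PCRModel:
    """Center features, project on principal components, least squares.

    The component count is chosen by Monte Carlo CV over 1..c_max with a
    single SVD per CV fold shared across candidates.
    """
    config = config or ModelConfig("PCR")
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 training cells and >= 1 feature")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features have zero variance")
    n, p = X.shape
    c_max = min(n - 2, p, config.max_components)
    c_max = max(c_max, 1)
    if config.grid is not None:
        candidates = [g["n_components"] for g in config.grid]
    else:
        candidates = list(range(1, c_max + 1))

    if len(candidates) > 1 and n >= 8:
        cache: dict[int, tuple] = {}

        def fit_predict(c, tr, va, fold):
            if fold not in cache:
                Xtr = X[tr]
                mu = Xtr.mean(axis=0)
                U, s, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
                cache[fold] = (mu, U, s, Vt, y[tr].mean(), y[tr] - y[tr].mean())
            mu, U, s, Vt, ybar, yc = cache[fold]
            rank = int(np.sum(s > s[0] * 1e-12)) if len(s) else 0
            cc = min(c, rank)
            coef = (U[:, :cc].T @ yc) / s[:cc]
            return (X[va] - mu) @ Vt[:cc].T @ coef + ybar

        chosen = monte_carlo_cv(
            candidates, X, y, fit_predict, k=config.cv_folds,
            val_frac=config.cv_val_frac, seed=config.seed,
        )
    else:
        chosen = candidates[0] if config.grid is not None else c_max

    mu = X.mean(axis=0)
    V, coef, intercept = _pcr_solve(X - mu, y, chosen)
    return PCRModel(X_train.columns.astype(str), mu, V, coef, intercept, V.shape[1])


class SVRModel:
    """Support vector regression with training-set standardization."""

    def __init__(self, feature_names, mean, scale, est: SVR, params, family):
        self.feature_names = list(feature_names)
        self.mean_ = mean
        self.scale_ = scale
        self.est_ = est
        self.chosen_params = params
        self.family = family

    def predict(self, X_test) -> np.ndarray:
        X = _align(X_test, self.feature_names)
        return self.est_.predict((X - self.mean_) / self.scale_)


def _standardizer(X: np.ndarray, with_std: bool) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    if not with_std:
        return mu, np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return mu, sd


def fit_svr(X_train: pd.DataFrame, y_train, config: ModelConfig) -> SVRModel:
    """Epsilon-insensitive SVR, grid resolved by Monte Carlo CV."""
    if config.family not in ("SVR_LINEAR", "SVR_RBF"):
        raise ValueError(f"fit_svr got family {config.family!r}")
    kernel = "linear" if config.family == "SVR_LINEAR" else "rbf"
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 training cells and >= 1 feature")
    mu, sd = _standardizer(X, config.standardize)
    Xs = (X - mu) / sd
    grid = config.resolved_grid()

    def make(params) -> SVR:
        kw = {"kernel": kernel, "C": params["C"], "epsilon": params["epsilon"]}
        if kernel == "rbf":
            kw["gamma"] = params["gamma"]
        return SVR(**kw)

    if len(grid) > 1 and len(y) >= 8:
        def fit_predict(params, tr, va, fold):
            est = make(params)
            est.fit(Xs[tr], y[tr])
            return est.predict(Xs[va])

        chosen = monte_carlo_cv(
            grid, Xs, y, fit_predict, k=config.cv_folds,
            val_frac=config.cv_val_frac, seed=config.seed,
        )
    else:
        chosen = grid[0]
    est = make(chosen)
    est.fit(Xs, y)
    return SVRModel(X_train.columns.astype(str), mu, sd, est, chosen, config.family)


class _TinyNet:
    """Single hidden layer (ReLU) with inverted dropout, full-batch Adam."""

    def __init__(self, n_in: int, n_hidden: int, dropout: float, seed: int):
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0, np.sqrt(2.0 / n_hidden), size=(n_hidden, 1))
        self.b2 = np.zeros(1)
        self.dropout = dropout
        self.rng = rng
        self.converged = True

    def _forward(self, X, train: bool):
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        if train and self.dropout > 0:
            mask = (self.rng.random(H.shape) >= self.dropout) / (1.0 - self.dropout)
            H = H * mask
        return H, (H @ self.W2 + self.b2).ravel()

    def fit(self, X, y, epochs: int, lr: float):
        params = [self.W1, self.b1, self.W2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = len(y)
        first_loss = None
        loss = np.inf
        for t in range(1, epochs + 1):
            H, out = self._forward(X, train=True)
            err = out - y
            loss = float(np.mean(err**2))
            if first_loss is None:
                first_loss = loss
            g_out = (2.0 / n) * err[:, None]
            gW2 = H.T @ g_out
            gb2 = g_out.sum(axis=0)
            gH = g_out @ self.W2.T
            gH[H <= 0] = 0.0
            gW1 = X.T @ gH
            gb1 = gH.sum(axis=0)
            for i, g in enumerate([gW1, gb1, gW2, gb2]):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g**2
                mh = m[i] / (1 - b1**t)
                vh = v[i] / (1 - b2**t)
                params[i] -= lr * mh / (np.sqrt(vh) + eps)
        if not np.isfinite(loss) or (first_loss is not None and loss > first_loss):
            self.converged = False
        return self

    def predict(self, X):
        return self._forward(X, train=False)[1]


class ANNModel:
    """Single-hidden-layer net; carries a convergence flag, never silent."""

    family = "ANN"

    def __init__(self, feature_names, mean, scale, net, y_mean, y_scale, params):
        self.feature_names = list(feature_names)
        self.mean_ = mean
        self.scale_ = scale
        self.net_ = net
        self.y_mean_ = y_mean
        self.y_scale_ = y_scale
        self.chosen_params = params
        self.converged = net.converged

    def predict(self, X_test) -> np.ndarray:
        X = _align(X_test, self.feature_names)
        out = self.net_.predict((X - self.mean_) / self.scale_)
        return out * self.y_scale_ + self.y_mean_


def fit_ann(X_train: pd.DataFrame, y_train, config: ModelConfig | None = None) -> ANNModel:
    config = config or ModelConfig("ANN")
    X = X_train.to_numpy(dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 training cells and >= 1 feature")
    mu, sd = _standardizer(X, True)
    Xs = (X - mu) / sd
    y_mean, y_scale = float(y.mean()), float(y.std() or 1.0)
    ys = (y - y_mean) / y_scale
    grid = config.resolved_grid()

    def train_one(params, Xa, ya, seed):
        net = _TinyNet(Xa.shape[1], config.ann_hidden, params["dropout"], seed)
        return net.fit(Xa, ya, config.ann_epochs, config.ann_lr)

    if len(grid) > 1 and len(y) >= 8:
        def fit_predict(params, tr, va, fold):
            net = train_one(params, Xs[tr], ys[tr], config.seed + 7919 * fold)
            return net.predict(Xs[va])

        chosen = monte_carlo_cv(
            grid, Xs, ys, fit_predict, k=config.cv_folds,
            val_frac=config.cv_val_frac, seed=config.seed,
        )
    else:
        chosen = grid[0]
    net = train_one(chosen, Xs, ys, config.seed)
    model = ANNModel(X_train.columns.astype(str), mu, sd, net, y_mean, y_scale, chosen)
    if not model.converged:
        warnings.warn("ANN training did not reduce the loss; model flagged", stacklevel=2)
    return model


class HistMeanModel:
    """Least squares on one-hot histotype = per-histotype training means."""

    family = "HIST_MEAN"

    def __init__(self, group_means: pd.Series, global_mean: float):
        self.group_means = group_means
        self.global_mean = global_mean
        self.chosen_params = {}
        self.feature_names = list(group_means.index)

    def predict(self, annotation_test) -> np.ndarray:
        if isinstance(annotation_test, HistotypeAnnotation):
            labels = annotation_test.labels
        else:
            labels = pd.Series(annotation_test)
        out = labels.map(self.group_means)
        unseen = out.isna()
        if unseen.any():
            warnings.warn(
                f"{int(unseen.sum())} test cells from unseen histotypes; "
                "predicting the global training mean",
                stacklevel=2,
            )
            out[unseen] = self.global_mean
        return out.to_numpy(dtype=float)


def fit_histotype_mean(annotation_train, y_train) -> HistMeanModel:
    """Group-mean baseline: prediction = training-mean response of the histotype."""
    if isinstance(annotation_train, HistotypeAnnotation):
        labels = annotation_train.labels
    else:
        labels = pd.Series(annotation_train)
    y = pd.Series(np.asarray(y_train, dtype=float), index=labels.index)
    means = y.groupby(labels).mean()
    return HistMeanModel(means, float(y.mean()))


def predict(model, X_or_annotation) -> np.ndarray:
    """Predict held-out responses; no refitting, name-based alignment."""
    return model.predict(X_or_annotation)


def make_prediction_set(
    model,
    X_or_annotation,
    y_measured: pd.Series,
    drug: str = "drug",
    split_index: int = 0,
    feature_method: str = "",
) -> PredictionSet:
    pred = model.predict(X_or_annotation)
    return PredictionSet(
        [str(c) for c in y_measured.index],
        y_measured.to_numpy(dtype=float),
        np.asarray(pred, dtype=float),
        drug=drug,
        split_index=split_index,
        family=model.family,
        feature_method=feature_method,
    )
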