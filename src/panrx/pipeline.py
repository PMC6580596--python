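"""Grid orchestration: drugs x splits x feature methods x model families.

Every grid cell selects features on the training cells, tunes and fits on
the training cells, predicts the held-out test cells, and scores the
predictions. Cells fail independently (a failure is a recorded row, never
an aborted run); per-cell seeds derive deterministically from the master
seed and the cell coordinates, so execution order does not matter and a
killed run can resume from its output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as fs
from . import models as mod
from .cohort import (
    DataSplit,
    ExpressionMatrix,
    HistotypeAnnotation,
    ResponseTable,
    filter_censored,
    make_stratified_splits,
)
from .evaluate import WpcUndefinedError, spearman_eval, mad_eval, wpc_index
from .histostruct import cluster_entropy, cluster_features

logger = logging.getLogger(__name__)

__all__ = ["ExperimentGrid", "run_benchmark", "feature_count_sweep", "cell_seed"]

DEFAULT_COUNTS = (10, 55, 250, 500, 1000)


@dataclass
class ExperimentGrid:
    """The full experimental design for one benchmark run."""

    feature_methods: list[str] = field(default_factory=lambda: ["DEG"])
    families: list[str] = field(default_factory=lambda: ["PCR"])
    n_splits: int = 6
    train_frac: float = 0.75
    min_cells_per_histotype: int = 4
    alpha: float = 0.05
    mrmr_k: int = 1000
    counts: tuple[int, ...] = DEFAULT_COUNTS
    seed: int = 0
    out_dir: str | None = None
    model_configs: dict = field(default_factory=dict)  # family -> ModelConfig kwargs

    def __post_init__(self) -> None:
        for m in self.feature_methods:
            if m not in fs.METHODS:
                raise ValueError(f"unknown feature method {m!r}")
        for f in self.families:
            if f not in mod.FAMILIES:
                raise ValueError(f"unknown model family {f!r}")


def cell_seed(master: int, *coords) -> int:
    """Deterministic per-cell seed from the master seed and cell coordinates."""
    key = "|".join([str(master), *map(str, coords)]).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big")


def _model_config(grid: ExperimentGrid, family: str, seed: int) -> mod.ModelConfig:
    kwargs = dict(grid.model_configs.get(family, {}))
    kwargs.setdefault("seed", seed)
    return mod.ModelConfig(family, **kwargs)


def _deg_set(X_train, y_train, alpha: float) -> fs.FeatureSet:
    _, deg = fs.spearman_screen(X_train, y_train, alpha=alpha)
    return deg


def _feature_matrices(
    method: str,
    X: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    y_train: pd.Series,
    annotation: HistotypeAnnotation,
    alpha: float,
    mrmr_k: int,
    seed: int,
):
    """Resolve a feature method to aligned train/test matrices.

    Returns (X_train_f, X_test_f, n_features, uses_annotation).
    HIST_MEAN-style baselines bypass this and consume the annotation
    directly.
    """
    X_train = X.loc[train_ids]
    if method == "NOFS":
        sel = fs.FeatureSet("NOFS", [str(c) for c in X.columns])
    elif method == "DEG":
        sel = _deg_set(X_train, y_train, alpha)
    elif method == "BC":
        cutoff = fs.bonferroni_threshold(alpha, X.shape[1])
        _, sel = fs.spearman_screen(X_train, y_train, alpha=cutoff, method="BC")
    elif method == "MODT":
        sel = fs.select_moderated_t(X_train, y_train)
    elif method == "BS":
        sel = fs.select_bootstrap(X_train, y_train, alpha=alpha, seed=seed)
    elif method == "BS_HIST":
        sel = fs.select_bootstrap(
            X_train, y_train, alpha=alpha, consensus=0.5,
            stratify_histotype=True, annotation=annotation, seed=seed,
        )
    elif method == "MRMR":
        sel = fs.select_mrmr(X_train, y_train, k=min(mrmr_k, X.shape[1]))
    elif method in ("CTR1", "CTR2"):
        deg = _deg_set(X_train, y_train, alpha)
        sel = fs.make_control_features(X.columns, deg, method, seed=seed)
    elif method == "RCTR":
        deg = _deg_set(X_train, y_train, alpha)
        n = max(len(deg.probe_ids), 1)
        shuffled, sel = fs.shuffle_matrix(X, n, seed=seed)
        return shuffled.loc[train_ids], shuffled.loc[test_ids], n, False
    elif method == "HIST":
        onehot = fs.encode_histotype(annotation, list(X.index))
        return (
            onehot.loc[train_ids],
            onehot.loc[test_ids],
            onehot.shape[1],
            False,
        )
    else:
        raise ValueError(f"unknown feature method {method!r}")
    if not sel.probe_ids:
        raise ValueError(f"{method} selected zero features")
    return (
        X_train[sel.probe_ids],
        X.loc[test_ids, sel.probe_ids],
        len(sel.probe_ids),
        False,
    )


def _fit_and_predict(
    family: str,
    X_train_f,
    X_test_f,
    y_train: pd.Series,
    ann_train,
    ann_test,
    config: mod.ModelConfig,
):
    if family == "HIST_MEAN":
        model = mod.fit_histotype_mean(ann_train, y_train)
        return model, model.predict(ann_test)
    if family == "PCR":
        model = mod.fit_pcr(X_train_f, y_train, config)
    elif family in ("SVR_LINEAR", "SVR_RBF"):
        model = mod.fit_svr(X_train_f, y_train, config)
    elif family == "ANN":
        model = mod.fit_ann(X_train_f, y_train, config)
    else:
        raise ValueError(f"unknown family {family!r}")
    return model, model.predict(X_test_f)


def _run_cell(
    drug: str,
    split: DataSplit,
    method: str,
    family: str,
    X: pd.DataFrame,
    y: pd.Series,
    annotation: HistotypeAnnotation,
    grid: ExperimentGrid,
) -> dict:
    seed = cell_seed(grid.seed, drug, split.split_index, method, family)
    row = {
        "drug": drug,
        "split": split.split_index,
        "feature_method": method,
        "family": family,
        "seed": seed,
        "status": "ok",
        "error": "",
    }
    try:
        train_ids = [c for c in split.train_ids if c in y.index]
        test_ids = [c for c in split.test_ids if c in y.index]
        y_train, y_test = y.loc[train_ids], y.loc[test_ids]
        ann_train = annotation.subset(train_ids)
        ann_test = annotation.subset(test_ids)
        if family == "HIST_MEAN":
            Xtr = Xte = None
            row["n_features"] = ann_train.labels.nunique()
        else:
            Xtr, Xte, n_feat, _ = _feature_matrices(
                method, X, train_ids, test_ids, y_train, annotation,
                grid.alpha, grid.mrmr_k, seed,
            )
            row["n_features"] = n_feat
        config = _model_config(grid, family, seed)
        model, pred = _fit_and_predict(family, Xtr, Xte, y_train, ann_train, ann_test, config)
        ps = mod.PredictionSet(
            test_ids, y_test.to_numpy(), pred, drug=drug,
            split_index=split.split_index, family=family, feature_method=method,
        )
        rho, p = spearman_eval(ps)
        row.update(rho=rho, p=p, mad=mad_eval(ps))
        try:
            row["wpc"] = wpc_index(ps)
        except WpcUndefinedError:
            row["wpc"] = float("nan")
        row["chosen_params"] = json.dumps(model.chosen_params)
    except Exception as exc:  # failed cells are recorded, never fatal
        logger.warning("cell (%s, %s, %s, %s) failed: %s", drug, split.split_index, method, family, exc)
        row.update(status="failed", error=str(exc), rho=np.nan, p=np.nan,
                   mad=np.nan, wpc=np.nan, n_features=row.get("n_features", 0))
    return row


def _resume_keys(path: Path) -> set[tuple]:
    done = set()
    if path.exists():
        with open(path) as fh:
            for line in fh:
                r = json.loads(line)
                done.add((r["drug"], r["split"], r["feature_method"], r["family"]))
    return done


def run_benchmark(
    expr: ExpressionMatrix,
    responses: dict[str, ResponseTable],
    annotation: HistotypeAnnotation,
    grid: ExperimentGrid,
    splits: dict[str, list[DataSplit]] | None = None,
) -> pd.DataFrame:
    """Run the full grid; returns a long-format results table.

    ``splits`` may pre-specify the per-drug splits (e.g. from a file);
    otherwise they are built per drug from the censoring-filtered cells.
    """
    out_path = None
    done: set[tuple] = set()
    if grid.out_dir is not None:
        out_dir = Path(grid.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / "results.jsonl"
        done = _resume_keys(out_path)
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(
                {
                    "seed": grid.seed,
                    "feature_methods": grid.feature_methods,
                    "families": grid.families,
                    "n_splits": grid.n_splits,
                    "train_frac": grid.train_frac,
                    "alpha": grid.alpha,
                },
                fh,
                indent=1,
            )

    rows = []
    if out_path is not None and out_path.exists():
        with open(out_path) as fh:
            rows = [json.loads(line) for line in fh]

    for drug in sorted(responses):
        rt = filter_censored(responses[drug])
        cells = [c for c in rt.cell_ids if c in expr.values.index]
        y = rt.as_series().loc[cells]
        if splits is not None and drug in splits:
            drug_splits = splits[drug]
        else:
            drug_splits = make_stratified_splits(
                cells, annotation, n_splits=grid.n_splits,
                train_frac=grid.train_frac,
                min_cells_per_histotype=grid.min_cells_per_histotype,
                seed=cell_seed(grid.seed, drug, "splits"),
            )
        modeled = sorted({c for s in drug_splits for c in s.train_ids + s.test_ids})
        X = expr.values.loc[modeled]
        ann = annotation.subset(modeled)
        for split in drug_splits:
            for method in grid.feature_methods:
                for family in grid.families:
                    key = (drug, split.split_index, method, family)
                    if key in done:
                        continue
                    row = _run_cell(drug, split, method, family, X, y, ann, grid)
                    rows.append(row)
                    done.add(key)
                    if out_path is not None:
                        with open(out_path, "a") as fh:
                            fh.write(json.dumps(row) + "\n")
    return pd.DataFrame(rows)


def feature_count_sweep(
    expr: ExpressionMatrix,
    response: ResponseTable,
    annotation: HistotypeAnnotation,
    counts=DEFAULT_COUNTS,
    source: str = "DEG",
    families: list[str] | None = None,
    grid: ExperimentGrid | None = None,
    splits: list[DataSplit] | None = None,
    audit_entropy: bool = True,
    entropy_restarts: int = 3,
) -> pd.DataFrame:
    """Model performance and S_c as the feature count is subsampled down.

    Per split, the source set (DEG, CTR1 or CTR2 computed on the training
    cells) is subsampled to each count with a seeded draw; counts that
    exceed the source size are skipped with a warning.
    """
    if source not in ("DEG", "CTR1", "CTR2"):
        raise ValueError("sweep source must be DEG, CTR1 or CTR2")
    grid = grid or ExperimentGrid()
    families = families or grid.families
    rt = filter_censored(response)
    cells = [c for c in rt.cell_ids if c in expr.values.index]
    y = rt.as_series().loc[cells]
    if splits is None:
        splits = make_stratified_splits(
            cells, annotation, n_splits=grid.n_splits, train_frac=grid.train_frac,
            min_cells_per_histotype=grid.min_cells_per_histotype,
            seed=cell_seed(grid.seed, rt.drug, "splits"),
        )
    modeled = sorted({c for s in splits for c in s.train_ids + s.test_ids})
    X = expr.values.loc[modeled]
    ann = annotation.subset(modeled)
    k_hist = ann.labels.nunique()

    rows = []
    for split in splits:
        train_ids = [c for c in split.train_ids if c in y.index]
        test_ids = [c for c in split.test_ids if c in y.index]
        y_train, y_test = y.loc[train_ids], y.loc[test_ids]
        seed0 = cell_seed(grid.seed, rt.drug, split.split_index, source, "sweep")
        deg = _deg_set(X.loc[train_ids], y_train, grid.alpha)
        if source == "DEG":
            pool = deg
        else:
            pool = fs.make_control_features(X.columns, deg, source, seed=seed0)
        for count in counts:
            if count > len(pool.probe_ids):
                logger.warning(
                    "count %d exceeds %s pool of %d; skipped", count, source, len(pool.probe_ids)
                )
                continue
            rng = np.random.default_rng(cell_seed(seed0, count))
            probes = list(rng.choice(pool.probe_ids, size=count, replace=False))
            entry_base = {
                "drug": rt.drug, "split": split.split_index, "source": source,
                "count": count,
            }
            if audit_entropy:
                res = cluster_features(
                    X, probes, k=k_hist, n_restarts=entropy_restarts,
                    seed=cell_seed(seed0, count, "kmeans"),
                )
                s_c = cluster_entropy(res.assignments, ann)
                entry_base["S_c_raw"] = s_c
            for family in families:
                config = _model_config(grid, family, cell_seed(seed0, count, family))
                try:
                    model, pred = _fit_and_predict(
                        family, X.loc[train_ids, probes], X.loc[test_ids, probes],
                        y_train, ann.subset(train_ids), ann.subset(test_ids), config,
                    )
                    ps = mod.PredictionSet(
                        test_ids, y_test.to_numpy(), pred, drug=rt.drug,
                        split_index=split.split_index, family=family, feature_method=source,
                    )
                    rho, p = spearman_eval(ps)
                    rows.append({**entry_base, "family": family, "rho": rho, "p": p,
                                 "mad": mad_eval(ps), "status": "ok"})
                except Exception as exc:
                    logger.warning("sweep cell failed: %s", exc)
                    rows.append({**entry_base, "family": family, "rho": np.nan,
                                 "p": np.nan, "mad": np.nan, "status": "failed"})
    return pd.DataFrame(rows)
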