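"""Cohort containers, file I/O, preprocessing filters and stratified splits.

A cohort is three aligned tables: a cells x probes log-expression matrix,
a per-drug response table (log IC50 with a censoring flag), and a
histotype annotation mapping each cell to a tissue label. Loading aligns
everything on the intersection of cell identifiers and reports what was
dropped; preprocessing averages replicate measurements and removes cells
whose IC50 exceeded the maximum tested concentration; splitting reserves
a fixed fraction of every histotype for training.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ResponseTable",
    "HistotypeAnnotation",
    "DataSplit",
    "read_cohort",
    "average_replicates",
    "filter_censored",
    "make_stratified_splits",
    "make_disjoint_test_splits",
]


@dataclass
class ExpressionMatrix:
    """Cells x probes log-scale expression with aligned identifiers."""

    values: pd.DataFrame  # index = cell ids, columns = probe ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids in expression matrix: {dup[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(cells)])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="cell_id")

    @classmethod
    def from_file(cls, path) -> "ExpressionMatrix":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        bad = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric expression value at cell {row!r}, probe {col!r}"
            )
        if df.isna().any().any():
            col = df.columns[df.isna().any()][0]
            row = df.index[df[col].isna()][0]
            raise ValueError(f"missing expression value at cell {row!r}, probe {col!r}")
        return cls(df.astype(float))


@dataclass
class ResponseTable:
    """Per-cell log IC50 for one drug, with censoring flags.

    ``measurements`` optionally keeps the raw replicate rows the averaged
    table was built from (long format: cell_id, log_ic50).
    """

    cell_ids: list[str]
    log_ic50: np.ndarray
    censored: np.ndarray
    drug: str = "drug"
    measurements: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.log_ic50 = np.asarray(self.log_ic50, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if not (len(self.cell_ids) == len(self.log_ic50) == len(self.censored)):
            raise ValueError("response table columns have unequal lengths")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids in response table; average replicates first")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def as_series(self) -> pd.Series:
        return pd.Series(self.log_ic50, index=self.cell_ids, name="log_ic50")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_ids, "log_ic50": self.log_ic50, "censored": self.censored}
        )

    def subset(self, cells) -> "ResponseTable":
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [idx[c] for c in cells]
        return ResponseTable(
            [self.cell_ids[i] for i in rows],
            self.log_ic50[rows],
            self.censored[rows],
            drug=self.drug,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_file(cls, path, drug: str = "drug") -> "ResponseTable":
        df = pd.read_csv(path)
        if "cell_id" not in df.columns or "log_ic50" not in df.columns:
            raise ValueError("response file needs cell_id and log_ic50 columns")
        if not pd.api.types.is_numeric_dtype(pd.to_numeric(df["log_ic50"], errors="coerce")):
            raise ValueError("non-numeric log_ic50 values")
        if pd.to_numeric(df["log_ic50"], errors="coerce").isna().any():
            row = df.index[pd.to_numeric(df["log_ic50"], errors="coerce").isna()][0]
            raise ValueError(f"non-numeric log_ic50 at row {row}")
        censored = (
            df["censored"].astype(bool).to_numpy()
            if "censored" in df.columns
            else np.zeros(len(df), dtype=bool)
        )
        df = df.assign(censored=censored)
        if df["cell_id"].duplicated().any():
            return average_replicates(df, drug=drug)
        return cls(
            df["cell_id"].astype(str).tolist(),
            df["log_ic50"].to_numpy(dtype=float),
            censored,
            drug=drug,
        )


@dataclass
class HistotypeAnnotation:
    """cell_id -> histotype label."""

    labels: pd.Series  # index = cell ids, values = labels

    def __post_init__(self) -> None:
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate cell ids in histotype annotation")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.labels.index)

    def label_of(self, cell: str) -> str:
        return self.labels.loc[cell]

    def subset(self, cells) -> "HistotypeAnnotation":
        cells = list(cells)
        missing = [c for c in cells if c not in self.labels.index]
        if missing:
            raise KeyError(f"cells without histotype annotation: {missing[:5]}")
        return HistotypeAnnotation(self.labels.loc[cells])

    def counts(self) -> pd.Series:
        return self.labels.value_counts()

    def to_csv(self, path) -> None:
        self.labels.rename("histotype").rename_axis("cell_id").to_csv(path)

    @classmethod
    def from_file(cls, path) -> "HistotypeAnnotation":
        df = pd.read_csv(path)
        if "cell_id" not in df.columns or "histotype" not in df.columns:
            raise ValueError("annotation file needs cell_id and histotype columns")
        return cls(pd.Series(df["histotype"].values, index=df["cell_id"].astype(str)))


@dataclass
class DataSplit:
    """One train/test partition of the modeled cells (1-based index)."""

    split_index: int
    train_ids: list[str]
    test_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")

    def to_dict(self) -> dict:
        return {
            "split_index": self.split_index,
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
        }


def splits_to_json(splits: list[DataSplit], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in splits], fh, indent=1)


def splits_from_json(path) -> list[DataSplit]:
    with open(path) as fh:
        raw = json.load(fh)
    return [DataSplit(d["split_index"], d["train_ids"], d["test_ids"]) for d in raw]


def read_cohort(
    expr_path, response_path, annotation_path, drug: str = "drug"
) -> tuple[ExpressionMatrix, ResponseTable, HistotypeAnnotation]:
    """Load the three tables and align them on shared cell ids.

    Cells present in only some tables are dropped and logged. An empty
    intersection is a hard error.
    """
    expr = ExpressionMatrix.from_file(expr_path)
    resp = ResponseTable.from_file(response_path, drug=drug)
    ann = HistotypeAnnotation.from_file(annotation_path)

    shared = sorted(set(expr.cell_ids) & set(resp.cell_ids) & set(ann.cell_ids))
    if not shared:
        raise ValueError("no cell ids shared by expression, response and annotation")
    for name, ids in [
        ("expression", expr.cell_ids),
        ("response", resp.cell_ids),
        ("annotation", ann.cell_ids),
    ]:
        dropped = sorted(set(ids) - set(shared))
        if dropped:
            logger.warning("%d %s-only cells dropped: %s", len(dropped), name, dropped[:5])
    return (
        expr.subset_cells(shared),
        resp.subset(shared),
        ann.subset(shared),
    )


def average_replicates(rows: pd.DataFrame, drug: str = "drug") -> ResponseTable:
    """Collapse repeated (cell_id, log_ic50) measurements to per-cell means.

    A cell is flagged censored if any of its replicate rows is.
    """
    if "cell_id" not in rows.columns or "log_ic50" not in rows.columns:
        raise ValueError("need cell_id and log_ic50 columns")
    rows = rows.copy()
    if "censored" not in rows.columns:
        rows["censored"] = False
    grouped = rows.groupby("cell_id", sort=True).agg(
        log_ic50=("log_ic50", "mean"), censored=("censored", "any")
    )
    return ResponseTable(
        grouped.index.astype(str).tolist(),
        grouped["log_ic50"].to_numpy(),
        grouped["censored"].to_numpy(),
        drug=drug,
        measurements=rows[["cell_id", "log_ic50"]],
    )


def filter_censored(rt: ResponseTable) -> ResponseTable:
    """Drop cells whose IC50 exceeded the maximum tested concentration."""
    keep = ~rt.censored
    n_removed = int(rt.censored.sum())
    if keep.sum() == 0:
        raise ValueError("all cells censored; nothing to model")
    if n_removed:
        logger.info("removed %d censored cells (%d remain)", n_removed, int(keep.sum()))
    rows = np.flatnonzero(keep)
    return ResponseTable(
        [rt.cell_ids[i] for i in rows],
        rt.log_ic50[rows],
        rt.censored[rows],
        drug=rt.drug,
    )


def _retained_histotypes(
    cells: list[str], annotation: HistotypeAnnotation, min_cells: int
) -> dict[str, list[str]]:
    by_hist: dict[str, list[str]] = {}
    for c in cells:
        by_hist.setdefault(annotation.label_of(c), []).append(c)
    kept = {}
    for h, members in sorted(by_hist.items()):
        if len(members) < min_cells:
            logger.warning(
                "histotype %r excluded: %d cells < min %d", h, len(members), min_cells
            )
        else:
            kept[h] = members
    if not kept:
        raise ValueError("no histotype meets the minimum cell count")
    return kept


def make_stratified_splits(
    cells,
    annotation: HistotypeAnnotation,
    n_splits: int = 6,
    train_frac: float = 0.75,
    min_cells_per_histotype: int = 4,
    seed: int = 0,
) -> list[DataSplit]:
    """Independent random splits reserving train_frac of every histotype.

    Per histotype h with n_h cells, ceil(train_frac * n_h) go to train and
    the remainder to test (never leaving a retained histotype absent from
    either side). Histotypes below the minimum count are excluded from
    modeling entirely.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    cells = [str(c) for c in cells]
    by_hist = _retained_histotypes(cells, annotation, min_cells_per_histotype)

    streams = np.random.SeedSequence(seed).spawn(n_splits)
    splits = []
    for i, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        train: list[str] = []
        test: list[str] = []
        for _, members in sorted(by_hist.items()):
            order = list(rng.permutation(members))
            n_train = math.ceil(train_frac * len(order))
            n_train = min(n_train, len(order) - 1)  # keep histotype in test
            train.extend(order[:n_train])
            test.extend(order[n_train:])
        splits.append(DataSplit(i, sorted(train), sorted(test)))
    return splits


def make_disjoint_test_splits(
    cells,
    annotation: HistotypeAnnotation,
    n_folds: int = 4,
    min_cells_per_histotype: int = 4,
    seed: int = 0,
) -> list[DataSplit]:
    """Alternative mode: n_folds splits with pairwise-disjoint test sets.

    Each histotype's cells are partitioned into n_folds groups; fold i
    tests on group i and trains on the rest.
    """
    cells = [str(c) for c in cells]
    by_hist = _retained_histotypes(cells, annotation, max(min_cells_per_histotype, n_folds))
    rng = np.random.default_rng(seed)
    fold_members: list[list[str]] = [[] for _ in range(n_folds)]
    for _, members in sorted(by_hist.items()):
        order = rng.permutation(members)
        for j, cell in enumerate(order):
            fold_members[j % n_folds].append(str(cell))
    all_cells = sorted(c for ms in fold_members for c in ms)
    splits = []
    for i in range(n_folds):
        test = sorted(fold_members[i])
        train = sorted(set(all_cells) - set(test))
        splits.append(DataSplit(i + 1, train, test))
    return splits
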