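"""Synthetic expression/response cohorts with a controllable histotype effect.

The generator produces a cells x probes log-expression matrix in which a
configurable subset of probes carries per-histotype centroids, and a drug
response decomposed into a histotype mean effect, a gene-driven
cell-specific effect, and noise. The fraction of signal variance carried
by the histotype means is an explicit knob (``hist_var_share``), so the
downstream diagnostics can be validated against a known ground truth.

Generative model (before response noise):

    x_ig = m_g + a_{h(i),g} * [g is a histotype probe] + e_ig
    y_i  = u_i + v_i,   u_i = mu_{h(i)},  v_i = sum_g beta_g x_ig

with u and v empirically rescaled so that Var(u) = lambda * s2 and
Var(v) = (1 - lambda) * s2 over the generated cells (s2 = ``signal_var``).
Replicate measurements add independent noise per replicate; the reported
log IC50 is their mean. Censored cells are flagged, never dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, HistotypeAnnotation, ResponseTable

__all__ = ["CohortSpec", "GroundTruth", "generate_cohort", "generate_null_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``cells_per_histotype`` may be a single count or a per-histotype list,
    so skewed histotype distributions can be emulated.
    """

    n_histotypes: int
    cells_per_histotype: int | tuple[int, ...] | list[int]
    n_probes: int
    n_hist_probes: int
    n_resp_probes: int
    n_overlap_probes: int = 0
    hist_var_share: float = 0.5  # lambda
    noise_sd_expr: float = 1.0
    noise_sd_resp: float = 0.3
    censor_fraction: float = 0.0
    replicates: int = 1
    seed: int = 0
    centroid_sd: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    signal_var: float = 1.0

    def __post_init__(self) -> None:
        counts = dict(
            n_histotypes=self.n_histotypes,
            n_probes=self.n_probes,
            n_hist_probes=self.n_hist_probes,
            n_resp_probes=self.n_resp_probes,
            n_overlap_probes=self.n_overlap_probes,
            replicates=self.replicates,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_histotypes < 1:
            raise ValueError("need at least one histotype")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.n_overlap_probes > min(self.n_hist_probes, self.n_resp_probes):
            raise ValueError("overlap cannot exceed either probe group")
        if self.n_hist_probes + self.n_resp_probes - self.n_overlap_probes > self.n_probes:
            raise ValueError(
                "infeasible probe partition: hist + resp - overlap exceeds n_probes"
            )
        if not (0.0 <= self.hist_var_share <= 1.0):
            raise ValueError(f"hist_var_share must be in [0, 1], got {self.hist_var_share}")
        if not (0.0 <= self.censor_fraction < 1.0):
            raise ValueError("censor_fraction must be in [0, 1)")

    @property
    def cell_counts(self) -> list[int]:
        if isinstance(self.cells_per_histotype, int):
            return [self.cells_per_histotype] * self.n_histotypes
        counts = list(self.cells_per_histotype)
        if len(counts) != self.n_histotypes:
            raise ValueError("cells_per_histotype list length != n_histotypes")
        return counts

    @property
    def n_cells(self) -> int:
        return sum(self.cell_counts)


@dataclass
class GroundTruth:
    """The latent quantities a recovery test needs."""

    histotype_means: pd.Series  # rescaled mu_h actually used in y
    beta: pd.Series  # per-probe coefficients (0 outside resp probes)
    hist_probe_ids: list[str]
    resp_probe_ids: list[str]
    hist_component: pd.Series = field(repr=False, default=None)  # u_i per cell
    gene_component: pd.Series = field(repr=False, default=None)  # v_i per cell

    def to_json(self, path) -> None:
        payload = {
            "histotype_means": self.histotype_means.to_dict(),
            "beta": {k: v for k, v in self.beta.items() if v != 0.0},
            "hist_probe_ids": self.hist_probe_ids,
            "resp_probe_ids": self.resp_probe_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _layout(spec: CohortSpec, rng: np.random.Generator):
    """Deterministic probe partition and cell/histotype labeling."""
    probe_ids = np.array([f"P{j:06d}" for j in range(spec.n_probes)])
    perm = rng.permutation(spec.n_probes)
    hist_idx = perm[: spec.n_hist_probes]
    # overlap probes are the tail of the hist block
    overlap = hist_idx[spec.n_hist_probes - spec.n_overlap_probes :]
    fresh = perm[spec.n_hist_probes : spec.n_hist_probes + spec.n_resp_probes - spec.n_overlap_probes]
    resp_idx = np.concatenate([overlap, fresh]).astype(int)

    counts = spec.cell_counts
    labels = np.repeat([f"H{h:03d}" for h in range(spec.n_histotypes)], counts)
    cell_ids = np.array([f"C{i:05d}" for i in range(spec.n_cells)])
    hist_codes = np.repeat(np.arange(spec.n_histotypes), counts)
    return probe_ids, hist_idx, resp_idx, cell_ids, labels, hist_codes


def _expression(spec: CohortSpec, rng, hist_idx, hist_codes) -> np.ndarray:
    m = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_probes)
    X = np.tile(m, (spec.n_cells, 1))
    if len(hist_idx):
        A = rng.normal(0.0, spec.centroid_sd, size=(spec.n_histotypes, len(hist_idx)))
        X[:, hist_idx] += A[hist_codes]
    X += rng.normal(0.0, spec.noise_sd_expr, size=X.shape)
    return X


def _rescale(component: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Center and rescale to an exact empirical variance; returns scale used."""
    c = component - component.mean()
    v = c.var()
    if target_var <= 0 or v == 0:
        return np.zeros_like(c), 0.0
    scale = np.sqrt(target_var / v)
    return c * scale, scale


def _assemble_response(spec: CohortSpec, rng, X, hist_codes, resp_idx, probe_ids):
    lam = spec.hist_var_share
    mu_raw = rng.normal(0.0, 1.0, size=spec.n_histotypes)
    u_raw = mu_raw[hist_codes]
    u, u_scale = _rescale(u_raw, lam * spec.signal_var)

    beta = np.zeros(spec.n_probes)
    if len(resp_idx):
        beta[resp_idx] = rng.normal(0.0, 1.0, size=len(resp_idx))
    v_raw = X @ beta
    v, v_scale = _rescale(v_raw, (1.0 - lam) * spec.signal_var)

    signal = u + v
    mu_used = (mu_raw - u_raw.mean()) * u_scale
    beta_used = beta * v_scale

    reps = rng.normal(0.0, spec.noise_sd_resp, size=(spec.n_cells, spec.replicates))
    y_reps = signal[:, None] + reps
    y = y_reps.mean(axis=1)

    gt_means = pd.Series(mu_used, index=[f"H{h:03d}" for h in range(spec.n_histotypes)])
    gt_beta = pd.Series(beta_used, index=probe_ids)
    return y, y_reps, u, v, gt_means, gt_beta


def _finish(spec: CohortSpec, rng, X, y, y_reps, probe_ids, cell_ids, labels):
    n_cens = int(round(spec.censor_fraction * spec.n_cells))
    censored = np.zeros(spec.n_cells, dtype=bool)
    if n_cens:
        censored[rng.choice(spec.n_cells, size=n_cens, replace=False)] = True

    expr = ExpressionMatrix(pd.DataFrame(X, index=cell_ids, columns=probe_ids))
    measurements = pd.DataFrame(
        {
            "cell_id": np.repeat(cell_ids, spec.replicates),
            "log_ic50": y_reps.ravel(),
        }
    )
    resp = ResponseTable(
        list(cell_ids), y, censored, drug="synthetic", measurements=measurements
    )
    ann = HistotypeAnnotation(pd.Series(labels, index=cell_ids))
    return expr, resp, ann


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ResponseTable, HistotypeAnnotation, GroundTruth]:
    """Generate a cohort with the structured response model; seeded, deterministic."""
    rng = np.random.default_rng(spec.seed)
    probe_ids, hist_idx, resp_idx, cell_ids, labels, hist_codes = _layout(spec, rng)
    X = _expression(spec, rng, hist_idx, hist_codes)
    y, y_reps, u, v, gt_means, gt_beta = _assemble_response(
        spec, rng, X, hist_codes, resp_idx, probe_ids
    )
    expr, resp, ann = _finish(spec, rng, X, y, y_reps, probe_ids, cell_ids, labels)
    gt = GroundTruth(
        histotype_means=gt_means,
        beta=gt_beta,
        hist_probe_ids=list(probe_ids[hist_idx]),
        resp_probe_ids=list(probe_ids[resp_idx]),
        hist_component=pd.Series(u, index=cell_ids),
        gene_component=pd.Series(v, index=cell_ids),
    )
    return expr, resp, ann, gt


def generate_null_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ResponseTable, HistotypeAnnotation, GroundTruth]:
    """Same expression structure, but y independent of expression and histotype."""
    rng = np.random.default_rng(spec.seed)
    probe_ids, hist_idx, resp_idx, cell_ids, labels, hist_codes = _layout(spec, rng)
    X = _expression(spec, rng, hist_idx, hist_codes)
    # consume the same stream draws as the structured path would not — the
    # null response is drawn fresh and owes nothing to X
    signal = rng.normal(0.0, np.sqrt(spec.signal_var), size=spec.n_cells)
    y_reps = signal[:, None] + rng.normal(
        0.0, spec.noise_sd_resp, size=(spec.n_cells, spec.replicates)
    )
    y = y_reps.mean(axis=1)
    expr, resp, ann = _finish(spec, rng, X, y, y_reps, probe_ids, cell_ids, labels)
    gt = GroundTruth(
        histotype_means=pd.Series(
            np.zeros(spec.n_histotypes), index=[f"H{h:03d}" for h in range(spec.n_histotypes)]
        ),
        beta=pd.Series(np.zeros(spec.n_probes), index=probe_ids),
        hist_probe_ids=list(probe_ids[hist_idx]),
        resp_probe_ids=list(probe_ids[resp_idx]),
        hist_component=pd.Series(np.zeros(spec.n_cells), index=cell_ids),
        gene_component=pd.Series(np.zeros(spec.n_cells), index=cell_ids),
    )
    return expr, resp, ann, gt


def write_cohort(out_dir, expr, resp, ann, gt: GroundTruth | None = None) -> None:
    """Write the standard cohort tables (and ground truth) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_tsv(out / "expression.tsv")
    resp.to_csv(out / "response.csv")
    ann.to_csv(out / "annotation.csv")
    if gt is not None:
        gt.to_json(out / "ground_truth.json")


def spec_from_dict(d: dict) -> CohortSpec:
    allowed = {f for f in CohortSpec.__dataclass_fields__}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown cohort spec fields: {sorted(unknown)}")
    return CohortSpec(**d)
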