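"""Floor transform, PCA replicate screening, and time-point DEG calling.

The contrast model is a per-gene one-way fixed-effects fit over the
time-point groups: each treated time point is compared with the 0 h
control as a difference of group means, with a two-sided t statistic on
the pooled residual variance of all groups (df = n_samples - n_groups).
A gene is differentially expressed at a time point when |log2FC| >= 2.0
and P <= 0.01 (both inclusive, configurable); no across-gene multiplicity
adjustment is applied at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "DegTable",
    "QcReport",
    "DegSummary",
    "floor_transform",
    "detect_outlier_samples",
    "fit_timepoint_contrasts",
    "call_degs",
    "summarize_degs",
    "write_deg_table",
    "read_deg_table",
]


@dataclass
class DegTable:
    """Per-gene, per-time-point contrasts and (after calling) DEG flags.

    ``log2fc`` and ``p_value`` are genes x treated-time-point frames;
    ``direction`` holds {accumulating, declining, none} per cell.
    """

    log2fc: pd.DataFrame
    p_value: pd.DataFrame
    fc_threshold: float | None = None
    p_threshold: float | None = None
    is_deg: pd.DataFrame | None = None
    direction: pd.DataFrame | None = None
    deg_any: pd.Series | None = None

    @property
    def times(self) -> list[float]:
        return [float(c) for c in self.log2fc.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def deg_genes(self) -> list[str]:
        if self.deg_any is None:
            raise ValueError("DEG flags not filled; run call_degs first")
        return list(self.deg_any.index[self.deg_any])


@dataclass
class QcReport:
    """PCA variance spectrum and flagged replicate outliers."""

    pc_variance_fractions: np.ndarray
    outliers: list[dict] = field(default_factory=list)

    @property
    def flagged_samples(self) -> list[str]:
        return sorted({o["sample_id"] for o in self.outliers})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.outliers, columns=["sample_id", "component", "score", "robust_z", "rule"]
        )


class DegSummary(NamedTuple):
    table: pd.DataFrame  # index time_h, columns accumulating/declining/total
    union: int  # genes DEG at >= 1 time point


def floor_transform(matrix: ExpressionMatrix, floor: float = 4.0) -> ExpressionMatrix:
    """Replace values below ``floor`` with ``floor`` (idempotent)."""
    return ExpressionMatrix(matrix.data.clip(lower=floor))


def detect_outlier_samples(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    n_pcs: int = 2,
    z_cut: float = 3.0,
    floor_value: float = 4.0,
) -> QcReport:
    """PCA overview plus robust screening of replicate outliers.

    The variance spectrum of gene-centered data is reported for the PCA
    overview (``pc_variance_fractions``).  Flagging uses each sample's
    replicate deviation: the Euclidean distance between the sample and
    the per-gene median of its time-point group, restricted to genes
    whose values stay strictly above ``floor_value`` in every sample.
    A sample is flagged when the robust z (median/MAD over all samples)
    of its deviation exceeds ``z_cut``.  The floor restriction matters:
    clipping at the floor shrinks replicate noise on strongly
    down-regulated genes in treated samples, which would otherwise make
    control-group deviations look systematically large; the group median
    (rather than mean) keeps an outlier from dragging its replicate
    mates over the threshold.
    """
    design.validate_against(matrix)
    n_samples = matrix.n_samples
    if n_samples < 3:
        raise ValueError("need at least 3 samples for PCA screening")
    if n_samples < n_pcs + 1:
        raise ValueError(f"need at least n_pcs+1={n_pcs + 1} samples, have {n_samples}")

    centered = matrix.data.values - matrix.data.values.mean(axis=1, keepdims=True)
    _, s, _ = np.linalg.svd(centered.T, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 1e-12:
        return QcReport(pc_variance_fractions=np.zeros(n_samples))
    fractions = s**2 / total

    unclipped = (matrix.data.values > floor_value).all(axis=1)
    y = centered[unclipped].T  # samples x unclipped genes
    sample_times = {row.sample_id: row.time_h for row in design.table.itertuples()}
    times = np.array([sample_times[s] for s in matrix.sample_ids])
    n_genes_used = max(y.shape[1], 1)
    distances = np.zeros(n_samples)
    for i in range(n_samples):
        group = np.flatnonzero(times == times[i])
        group_median = np.median(y[group], axis=0)
        distances[i] = float(np.linalg.norm(y[i] - group_median) / np.sqrt(n_genes_used))

    outliers: list[dict] = []
    mad = stats.median_abs_deviation(distances, scale="normal")
    if mad > 1e-12:
        z = (distances - np.median(distances)) / mad
        for i in np.flatnonzero(z > z_cut):
            outliers.append(
                {
                    "sample_id": matrix.sample_ids[i],
                    "component": 0,
                    "score": float(distances[i]),
                    "robust_z": float(z[i]),
                    "rule": f"replicate deviation robust z > {z_cut}",
                }
            )
    if outliers:
        logger.warning("flagged replicate outliers: %s", sorted({o['sample_id'] for o in outliers}))
    return QcReport(pc_variance_fractions=fractions, outliers=outliers)


def fit_timepoint_contrasts(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    moderated: bool = False,
    prior_df: float = 4.0,
) -> DegTable:
    """Fit per-gene one-way contrasts of each treated time point vs control.

    With ``moderated=True`` the per-gene pooled variance is shrunk toward
    the median variance with ``prior_df`` pseudo-degrees of freedom (a
    fixed-prior variant of moderated statistics); off by default.
    """
    design.validate_against(matrix)
    times = design.times
    groups = {t: design.samples_at(t) for t in times}
    for t, samples in groups.items():
        if len(samples) < 2:
            raise ValueError(f"time point {t:g} h has {len(samples)} replicate(s); need >= 2")

    x = matrix.data
    n_total = matrix.n_samples
    n_groups = len(times)
    df = n_total - n_groups

    means = {t: x[groups[t]].mean(axis=1) for t in times}
    rss = np.zeros(matrix.n_genes)
    for t in times:
        block = x[groups[t]].values
        rss += ((block - means[t].values[:, None]) ** 2).sum(axis=1)
    s2 = rss / df
    df_eff = float(df)
    if moderated:
        s0 = float(np.median(s2))
        s2 = (prior_df * s0 + df * s2) / (prior_df + df)
        df_eff = df + prior_df

    zero_var = s2 <= 0.0
    if zero_var.any():
        logger.warning("%d gene(s) with zero pooled variance", int(zero_var.sum()))

    control = times[0]
    n0 = len(groups[control])
    fc_cols, p_cols = {}, {}
    for t in times[1:]:
        fc = means[t].values - means[control].values
        se = np.sqrt(s2 * (1.0 / len(groups[t]) + 1.0 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = fc / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df_eff)
        p = np.where(zero_var, np.where(fc != 0.0, 0.0, 1.0), p)
        fc_cols[t] = fc
        p_cols[t] = p

    idx = matrix.data.index
    return DegTable(
        log2fc=pd.DataFrame(fc_cols, index=idx),
        p_value=pd.DataFrame(p_cols, index=idx),
    )


def call_degs(
    table: DegTable, fc_threshold: float = 2.0, p_threshold: float = 0.01
) -> DegTable:
    """Flag DEGs: |log2FC| >= fc_threshold and P <= p_threshold, inclusive."""
    if fc_threshold < 0 or p_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    is_deg = (table.log2fc.abs() >= fc_threshold) & (table.p_value <= p_threshold)
    direction = pd.DataFrame(
        np.where(is_deg, np.where(table.log2fc > 0, "accumulating", "declining"), "none"),
        index=table.log2fc.index,
        columns=table.log2fc.columns,
    )
    return DegTable(
        log2fc=table.log2fc,
        p_value=table.p_value,
        fc_threshold=fc_threshold,
        p_threshold=p_threshold,
        is_deg=is_deg,
        direction=direction,
        deg_any=is_deg.any(axis=1),
    )


def summarize_degs(table: DegTable) -> DegSummary:
    """Per-time-point accumulating/declining/total counts plus the union."""
    if table.direction is None or table.deg_any is None:
        raise ValueError("DEG flags not filled; run call_degs first")
    rows = []
    for col in table.direction.columns:
        acc = int((table.direction[col] == "accumulating").sum())
        dec = int((table.direction[col] == "declining").sum())
        rows.append({"time_h": float(col), "accumulating": acc, "declining": dec, "total": acc + dec})
    frame = pd.DataFrame(rows).set_index("time_h")
    return DegSummary(table=frame, union=int(table.deg_any.sum()))


def write_deg_table(table: DegTable, path: str | Path) -> None:
    parts = {}
    for col in table.log2fc.columns:
        tag = f"{float(col):g}h"
        parts[f"log2fc_{tag}"] = table.log2fc[col]
        parts[f"p_{tag}"] = table.p_value[col]
        if table.is_deg is not None:
            parts[f"is_deg_{tag}"] = table.is_deg[col].astype(int)
    frame = pd.DataFrame(parts)
    if table.deg_any is not None:
        frame["deg_any"] = table.deg_any.astype(int)
    frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_deg_table(path: str | Path) -> DegTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    times = sorted(
        float(c[len("log2fc_") : -1]) for c in frame.columns if c.startswith("log2fc_")
    )
    fc = pd.DataFrame({t: frame[f"log2fc_{t:g}h"] for t in times})
    p = pd.DataFrame({t: frame[f"p_{t:g}h"] for t in times})
    table = DegTable(log2fc=fc, p_value=p)
    if f"is_deg_{times[0]:g}h" in frame.columns:
        is_deg = pd.DataFrame({t: frame[f"is_deg_{t:g}h"].astype(bool) for t in times})
        table.is_deg = is_deg
        table.direction = pd.DataFrame(
            np.where(is_deg, np.where(fc > 0, "accumulating", "declining"), "none"),
            index=fc.index,
            columns=fc.columns,
        )
        table.deg_any = is_deg.any(axis=1)
    return table
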