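"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and sample designs travel as TSV, gene sets as GMT,
gene -> category annotations as two-column TSV, and networks as edge-list
TSV, SIF or GraphML.  All writers emit sorted, diff-stable output.  Gene
identifiers are opaque case-sensitive strings (AGI codes in practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SampleDesign",
    "GeneSet",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "write_network",
]


@dataclass
class ExpressionMatrix:
    """Dense log2-scale expression table, genes (rows) by samples (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.isna().any().any():
            cell = next(
                (g, s)
                for g in self.data.index
                for s in self.data.columns
                if pd.isna(self.data.at[g, s])
            )
            raise ValueError(f"missing value at gene {cell[0]!r}, sample {cell[1]!r}")
        nonnum = [c for c in self.data.columns if not np.issubdtype(self.data[c].dtype, np.number)]
        if nonnum:
            raise ValueError(f"non-numeric columns: {nonnum}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)].copy())

    def drop_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.drop(columns=list(samples)))


@dataclass
class SampleDesign:
    """Mapping of sample ids to incubation time (hours) and replicate index."""

    table: pd.DataFrame  # columns: sample_id, time_h, replicate

    def __post_init__(self) -> None:
        required = {"sample_id", "time_h", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        self.table = self.table.copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["time_h"] = self.table["time_h"].astype(float)
        self.table["replicate"] = self.table["replicate"].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def times(self) -> list[float]:
        return sorted(self.table["time_h"].unique())

    def samples_at(self, time_h: float) -> list[str]:
        sel = self.table[self.table["time_h"] == time_h]
        return list(sel["sample_id"])

    def drop_samples(self, samples: Iterable[str]) -> "SampleDesign":
        drop = set(samples)
        return SampleDesign(
            self.table[~self.table["sample_id"].isin(drop)].reset_index(drop=True)
        )

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        design_samples = set(self.sample_ids)
        matrix_samples = set(matrix.sample_ids)
        if design_samples != matrix_samples:
            raise ValueError(
                f"design/matrix sample mismatch: only in design "
                f"{sorted(design_samples - matrix_samples)}, only in matrix "
                f"{sorted(matrix_samples - design_samples)}"
            )
        if 0.0 not in self.table["time_h"].values:
            raise ValueError("design lacks the control time point (0 h)")

    def replicate_means(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        """Per-gene mean profile over time points (genes x times)."""
        cols = {}
        for t in self.times:
            cols[t] = matrix.data[self.samples_at(t)].mean(axis=1)
        return pd.DataFrame(cols)


@dataclass
class GeneSet:
    name: str
    description: str = ""
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            seen: set[str] = set()
            deduped = []
            for m in self.members:
                if m not in seen:
                    seen.add(m)
                    deduped.append(m)
            logger.warning(
                "gene set %s: %d duplicate members removed",
                self.name,
                len(self.members) - len(deduped),
            )
            self.members = deduped

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# TSV matrix / design


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise ValueError(f"{path}: malformed header (no sample columns)")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric cell in column {col!r}"
                + (f", row {bad[0]!r}" if len(bad) else "")
            )
    try:
        return ExpressionMatrix(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, float_format="%g")


# ---------------------------------------------------------------------------
# GMT gene sets and annotation tables


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, 'name<TAB>description<TAB>members...'."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            sets.append(GeneSet(name=fields[0], description=fields[1], members=fields[2:]))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in sorted(sets, key=lambda s: s.name):
            handle.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> category TSV (many-to-many)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene", "category"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "category"])
    return df[["gene", "category"]].astype(str)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.sort_values(["gene", "category"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export


def _canonical_edges(net) -> list[tuple[str, str, float]]:
    edges = []
    for u, v, attrs in net.graph.edges(data=True):
        a, b = sorted((u, v))
        edges.append((a, b, float(attrs.get("r", np.nan))))
    return sorted(edges)


def write_network(net, path: str | Path, format: str = "edge_tsv") -> None:
    """Export a co-expression network.

    Formats: ``edge_tsv`` (source, target, r), ``sif`` (relation token
    ``co``; isolated nodes one per line), ``graphml`` (node attributes
    degree/hub/som_bin/region, edge attribute r).  Undirected edges are
    written once, endpoints in lexicographic order.
    """
    path = Path(path)
    edges = _canonical_edges(net)
    if format == "edge_tsv":
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("source\ttarget\tr\n")
            for a, b, r in edges:
                handle.write(f"{a}\t{b}\t{r:.10g}\n")
    elif format == "sif":
        linked = {n for a, b, _ in edges for n in (a, b)}
        with open(path, "w", encoding="utf-8") as handle:
            for a, b, _ in edges:
                handle.write(f"{a}\tco\t{b}\n")
            for node in sorted(set(net.graph.nodes) - linked):
                handle.write(f"{node}\n")
    elif format == "graphml":
        out = nx.Graph()
        for node in sorted(net.graph.nodes):
            attrs = net.graph.nodes[node]
            out.add_node(
                node,
                degree=int(net.graph.degree(node)),
                hub=bool(attrs.get("hub", False)),
                som_bin=int(attrs.get("som_bin", -1)),
                region=str(attrs.get("region", "none")),
            )
        for a, b, r in edges:
            out.add_edge(a, b, r=r)
        nx.write_graphml(out, path)
    else:
        raise ValueError(f"unknown network format: {format!r}")
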