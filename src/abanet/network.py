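"""Hard-threshold Pearson co-expression network over DEGs.

Edges join gene pairs whose Pearson correlation exceeds a fixed cutoff
(default r > 0.97, strict, on per-time-point replicate-mean profiles).
Degree is the only centrality used: the ``hub_k`` nodes of highest degree
(default 100) are the hubs.  Nodes inherit an early-/late-response region
label from their SOM bin: a bin whose mean profile completes at least
half of its dynamic range in the first treated time point is early
response (ER), otherwise late response (LR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionNetwork",
    "CorrelationResult",
    "HubResult",
    "correlation_matrix",
    "build_network",
    "node_degrees",
    "identify_hubs",
    "connected_components",
    "partition_regions",
]


@dataclass
class CoexpressionNetwork:
    graph: nx.Graph
    threshold: float
    mode: str  # "positive" | "absolute"
    basis: str = "replicate_means"
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def hubs(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("hub"))


class CorrelationResult(NamedTuple):
    r: pd.DataFrame  # symmetric genes x genes
    excluded: list[str]  # zero-profile-variance genes


class HubResult(NamedTuple):
    hubs: list[str]
    degree_range: tuple[int, int]  # (min, max) over the selected set


def correlation_matrix(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    genes: Sequence[str],
    basis: str = "replicate_means",
) -> CorrelationResult:
    """Pairwise Pearson r between gene profiles.

    ``replicate_means`` (default) correlates 5-point per-time mean
    profiles; ``all_samples`` uses the full replicate-level vectors.
    Genes with zero profile variance are excluded with a warning.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    sub = matrix.subset_genes(list(genes))
    if basis == "replicate_means":
        profiles = design.replicate_means(sub)
    elif basis == "all_samples":
        profiles = sub.data
    else:
        raise ValueError(f"unknown correlation basis: {basis!r}")
    if profiles.shape[1] < 3:
        raise ValueError(f"need >= 3 profile points, have {profiles.shape[1]}")

    variances = profiles.var(axis=1, ddof=0)
    excluded = sorted(variances.index[variances <= 1e-300])
    if excluded:
        logger.warning("excluding %d zero-variance gene(s) from correlation", len(excluded))
        profiles = profiles.drop(index=excluded)
    if profiles.shape[0] == 0:
        raise ValueError("all genes have zero profile variance")

    r = np.corrcoef(profiles.values)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    frame = pd.DataFrame(r, index=profiles.index, columns=profiles.index)
    return CorrelationResult(r=frame, excluded=excluded)


def build_network(
    r_table: pd.DataFrame, threshold: float = 0.97, mode: str = "positive"
) -> CoexpressionNetwork:
    """Threshold a correlation table into an undirected simple graph.

    Edge (u, v) iff r > threshold (mode ``positive``) or |r| > threshold
    (mode ``absolute``); strictly above, matching a hard filtration.  All
    genes in the table become nodes, isolated or not.
    """
    if not (-1.0 < threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside (-1, 1]")
    if mode not in ("positive", "absolute"):
        raise ValueError(f"unknown correlation mode: {mode!r}")
    if not r_table.index.equals(r_table.columns):
        raise ValueError("correlation table must be square with matching labels")

    genes = list(r_table.index)
    values = r_table.values
    crit = np.abs(values) if mode == "absolute" else values
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = crit[iu, ju] > threshold

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    graph.add_edges_from(
        (genes[i], genes[j], {"r": float(values[i, j])})
        for i, j in zip(iu[keep], ju[keep])
    )
    return CoexpressionNetwork(graph=graph, threshold=threshold, mode=mode)


def node_degrees(net: CoexpressionNetwork) -> dict[str, int]:
    """Degree per node (count of incident edges); stored as a node attribute."""
    degrees = {n: int(d) for n, d in net.graph.degree()}
    nx.set_node_attributes(net.graph, degrees, "degree")
    return degrees


def identify_hubs(net: CoexpressionNetwork, hub_k: int = 100) -> HubResult:
    """Top ``hub_k`` nodes by degree (ties broken by gene id, ascending).

    Returns the hub list and the (min, max) degree of the selected set;
    marks nodes with a boolean ``hub`` attribute.
    """
    if hub_k <= 0:
        raise ValueError("hub_k must be positive")
    degrees = node_degrees(net)
    ranked = sorted(degrees, key=lambda g: (-degrees[g], g))
    hubs = ranked[: min(hub_k, len(ranked))]
    nx.set_node_attributes(net.graph, False, "hub")
    nx.set_node_attributes(net.graph, {g: True for g in hubs}, "hub")
    if hubs:
        selected = [degrees[g] for g in hubs]
        degree_range = (min(selected), max(selected))
    else:
        degree_range = (0, 0)
    return HubResult(hubs=hubs, degree_range=degree_range)


def connected_components(net: CoexpressionNetwork) -> tuple[list[set[str]], bool]:
    """Maximal connected node sets (largest first) and a single-component flag."""
    comps = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), sorted(c)))
    return comps, len(comps) == 1


def partition_regions(
    net: CoexpressionNetwork,
    som_bins: Mapping[str, int],
    matrix: ExpressionMatrix,
    design: SampleDesign,
    earliness_cut: float = 0.5,
) -> tuple[dict[str, str], dict[int, str], dict[int, float]]:
    """Label SOM bins (and their nodes) early response / late response.

    For each bin, earliness E = |mean(t1) - mean(t0)| / (max - min) of the
    bin's mean member profile, t1 being the first treated time point.
    E >= earliness_cut -> ER, otherwise LR; zero-dynamic-range bins -> none.
    Nodes inherit the label of their bin via the ``region`` attribute.
    """
    missing = [n for n in net.graph.nodes if n not in som_bins]
    if missing:
        raise ValueError(f"missing SOM assignment for nodes: {missing[:5]}")

    profiles = design.replicate_means(matrix)
    bin_label: dict[int, str] = {}
    bin_earliness: dict[int, float] = {}
    for unit in sorted({som_bins[n] for n in net.graph.nodes}):
        members = [n for n in net.graph.nodes if som_bins[n] == unit]
        mean_profile = profiles.loc[members].mean(axis=0).values
        dynamic_range = float(mean_profile.max() - mean_profile.min())
        if dynamic_range <= 1e-12:
            bin_label[unit] = "none"
            bin_earliness[unit] = 0.0
            continue
        e = abs(mean_profile[1] - mean_profile[0]) / dynamic_range
        bin_earliness[unit] = float(e)
        bin_label[unit] = "ER" if e >= earliness_cut else "LR"

    regions = {n: bin_label[som_bins[n]] for n in net.graph.nodes}
    nx.set_node_attributes(net.graph, regions, "region")
    nx.set_node_attributes(net.graph, {n: int(som_bins[n]) for n in net.graph.nodes}, "som_bin")
    return regions, bin_label, bin_earliness
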