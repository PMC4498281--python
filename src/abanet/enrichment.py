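"""Gene-set overlays, hub enrichment and over-representation analysis.

Gene sets are projected onto the co-expression network (coverage and
per-region tallies), multi-set intersections are computed over a gene
universe, and over-representation is tested with the one-sided
hypergeometric upper tail.  ORA across GO-style categories applies
Bonferroni control (default alpha 0.05); enrichment of a set within the
network hubs is tested at alpha 0.01 without multiplicity correction by
default, since only a handful of sets are typically examined there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet
from .network import CoexpressionNetwork

__all__ = [
    "OverlayEntry",
    "EnrichmentRow",
    "project_gene_sets",
    "intersect_overlays",
    "hypergeometric_upper_tail",
    "hub_set_enrichment",
    "run_ora",
    "enrichment_frame",
]


@dataclass
class OverlayEntry:
    set_name: str
    nodes_hit: int
    fraction: float  # of all network nodes
    region_counts: dict[str, int]  # ER / LR / none tallies among hit nodes
    absent: int  # set members not present in the network

    def as_dict(self) -> dict:
        d = {
            "set": self.set_name,
            "nodes_hit": self.nodes_hit,
            "fraction": self.fraction,
            "absent": self.absent,
        }
        for region in ("ER", "LR", "none"):
            d[f"n_{region}"] = self.region_counts.get(region, 0)
        return d


@dataclass
class EnrichmentRow:
    category: str
    k: int  # overlap with the selection
    K: int  # category size in the universe
    n: int  # selection size
    N: int  # universe size
    expected: float  # n * K / N
    ratio_obs_exp: float
    ratio_exp_obs: float
    p: float
    p_adj: float
    significant: bool


def project_gene_sets(
    net: CoexpressionNetwork, sets: Sequence[GeneSet]
) -> dict[str, OverlayEntry]:
    """Overlay gene sets on the network: coverage and per-region tallies.

    Membership flags are written onto nodes (attribute ``sets``); genes in
    a set but absent from the network are counted separately.
    """
    if not sets:
        raise ValueError("no gene sets to project")
    nodes = set(net.graph.nodes)
    result: dict[str, OverlayEntry] = {}
    for gs in sets:
        members = set(gs.members)
        hit = members & nodes
        for node in hit:
            tags = net.graph.nodes[node].setdefault("sets", [])
            if gs.name not in tags:
                tags.append(gs.name)
        region_counts: dict[str, int] = {}
        for node in hit:
            region = net.graph.nodes[node].get("region", "none")
            region_counts[region] = region_counts.get(region, 0) + 1
        result[gs.name] = OverlayEntry(
            set_name=gs.name,
            nodes_hit=len(hit),
            fraction=len(hit) / len(nodes) if nodes else 0.0,
            region_counts=region_counts,
            absent=len(members - nodes),
        )
    return result


def intersect_overlays(sets: Sequence[GeneSet], scope: Sequence[str]) -> list[str]:
    """Genes present in every set and in scope, sorted lexicographically."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets to intersect")
    common = set(scope)
    for gs in sets:
        common &= set(gs.members)
    return sorted(common)


def hypergeometric_upper_tail(k, K: int, n: int, N: int):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space.

    N: universe size, K: category size, n: selection size, k: overlap.
    ``k`` may be a scalar or an array of overlap counts.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    k_arr = np.asarray(k, dtype=int)
    if np.any(k_arr < 0) or np.any(k_arr > min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    p = stats.hypergeom.sf(k_arr - 1, N, K, n)
    return float(p) if np.ndim(k) == 0 else np.asarray(p, dtype=float)


def _row(category: str, k: int, K: int, n: int, N: int) -> EnrichmentRow:
    expected = n * K / N if N else 0.0
    return EnrichmentRow(
        category=category,
        k=k,
        K=K,
        n=n,
        N=N,
        expected=expected,
        ratio_obs_exp=k / expected if expected > 0 else float("inf") if k else 0.0,
        ratio_exp_obs=expected / k if k > 0 else float("inf") if expected else 0.0,
        p=hypergeometric_upper_tail(k, K, n, N),
        p_adj=1.0,
        significant=False,
    )


def hub_set_enrichment(
    net: CoexpressionNetwork,
    sets: Sequence[GeneSet],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> list[EnrichmentRow]:
    """Test each gene set for over-representation within the network hubs.

    Universe = network nodes, selection = hubs, category = set members
    present in the network.  Significance at ``alpha`` (strictly below);
    Bonferroni across the tested sets is optional and off by default.
    """
    hubs = set(net.hubs)
    if not hubs:
        raise ValueError("no hubs identified on the network")
    nodes = set(net.graph.nodes)
    rows = []
    for gs in sets:
        members = set(gs.members)
        row = _row(
            category=gs.name,
            k=len(members & hubs),
            K=len(members & nodes),
            n=len(hubs),
            N=len(nodes),
        )
        rows.append(row)
    m = len(rows) if bonferroni else 1
    for row in rows:
        row.p_adj = min(1.0, row.p * m)
        row.significant = row.p_adj < alpha
    return sorted(rows, key=lambda r: (r.p_adj, r.category))


def run_ora(
    selected: Sequence[str],
    universe: Sequence[str],
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    redundancy_prune: bool = False,
) -> list[EnrichmentRow]:
    """Hypergeometric ORA of a selection against gene -> category annotation.

    Categories with at least one selected member are tested; p values are
    Bonferroni-adjusted across all tested categories and rows are sorted
    by adjusted p.  ``redundancy_prune`` optionally drops categories whose
    (universe-restricted) member list is a subset of a strictly more
    significant category.
    """
    universe_set = set(universe)
    selected_set = set(selected)
    offenders = sorted(selected_set - universe_set)
    if offenders:
        raise ValueError(f"selected genes outside the universe: {offenders[:10]}")

    ann = annotation[annotation["gene"].isin(universe_set)]
    if not (set(ann["gene"]) & selected_set):
        raise ValueError("annotation covers no selected gene")
    by_cat = ann.groupby("category")["gene"].agg(set)

    rows = []
    members_of: dict[str, set[str]] = {}
    for category, members in by_cat.items():
        k = len(members & selected_set)
        if k == 0:
            continue
        members_of[category] = members
        rows.append(
            _row(category=category, k=k, K=len(members), n=len(selected_set), N=len(universe_set))
        )
    m = len(rows)
    for row in rows:
        row.p_adj = min(1.0, row.p * m)
        row.significant = row.p_adj < alpha
    rows.sort(key=lambda r: (r.p_adj, r.p, r.category))

    if redundancy_prune:
        kept: list[EnrichmentRow] = []
        for row in rows:
            if any(
                members_of[row.category] <= members_of[prev.category]
                and (prev.p_adj, prev.p) < (row.p_adj, row.p)
                for prev in kept
            ):
                continue
            kept.append(row)
        rows = kept
    return rows


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": r.category,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "expected": r.expected,
                "ratio_obs_exp": r.ratio_obs_exp,
                "ratio_exp_obs": r.ratio_exp_obs,
                "p": r.p,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
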