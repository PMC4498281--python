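"""Correlation, thresholded graph, degrees, hubs, components and regions."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from abanet import network as nm
from abanet.io import ExpressionMatrix, SampleDesign
from abanet.synthetic import SyntheticConfig, generate_dataset
from oracles import adjacency_from_r, pearson_r, union_find_components


def _design(times, reps=1):
    rows = [
        {"sample_id": f"t{t:g}_r{r}", "time_h": t, "replicate": r}
        for t in times
        for r in range(1, reps + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def _matrix(values, design, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(values))]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=design.sample_ids))


def test_self_correlation_is_one(default_dataset):
    matrix, design, truth, _ = default_dataset
    genes = truth.genes_of_class("ER_up")[:5]
    corr = nm.correlation_matrix(matrix, design, genes)
    assert np.allclose(np.diag(corr.r.values), 1.0)


def test_mirrored_templates_anticorrelate(clean_config):
    matrix, design, truth = generate_dataset(clean_config)
    genes = [truth.genes_of_class("ER_up")[0], truth.genes_of_class("ER_down")[0]]
    corr = nm.correlation_matrix(matrix, design, genes)
    assert corr.r.iloc[0, 1] == pytest.approx(-1.0)


def test_correlation_matches_direct_formula():
    """Random 5-point profiles against the explicit Pearson sum formula."""
    rng = np.random.default_rng(7)
    design = _design([0, 2, 12, 24, 72])
    values = rng.normal(7, 1, size=(10, 5))
    matrix = _matrix(values, design)
    corr = nm.correlation_matrix(matrix, design, matrix.gene_ids, basis="all_samples")
    for i in range(10):
        for j in range(i + 1, 10):
            assert corr.r.iloc[i, j] == pytest.approx(
                pearson_r(values[i], values[j]), abs=1e-12
            )


def test_zero_variance_genes_are_excluded():
    design = _design([0, 2, 12])
    matrix = _matrix([[5, 5, 5], [1, 2, 3], [3, 2, 1]], design)
    corr = nm.correlation_matrix(matrix, design, matrix.gene_ids)
    assert corr.excluded == ["g0"]
    assert list(corr.r.index) == ["g1", "g2"]


def test_correlation_input_validation(default_dataset):
    matrix, design, _, _ = default_dataset
    with pytest.raises(ValueError):
        nm.correlation_matrix(matrix, design, [])
    short_design = _design([0, 2])
    short = _matrix([[1, 2], [2, 1]], short_design)
    with pytest.raises(ValueError, match="3"):
        nm.correlation_matrix(short, short_design, short.gene_ids)


def test_noise_free_block_forms_a_clique(clean_config):
    matrix, design, truth = generate_dataset(clean_config)
    genes = truth.genes_of_class("ER_up")[:3]
    corr = nm.correlation_matrix(matrix, design, genes)
    net = nm.build_network(corr.r)
    assert net.n_edges == 3


def test_sign_handling_positive_vs_absolute(clean_config):
    matrix, design, truth = generate_dataset(clean_config)
    genes = [truth.genes_of_class("ER_up")[0], truth.genes_of_class("ER_down")[0]]
    corr = nm.correlation_matrix(matrix, design, genes)
    assert nm.build_network(corr.r, mode="positive").n_edges == 0
    assert nm.build_network(corr.r, mode="absolute").n_edges == 1


def test_threshold_is_strict():
    r = pd.DataFrame(
        [[1.0, 0.97], [0.97, 1.0]], index=["a", "b"], columns=["a", "b"]
    )
    assert nm.build_network(r, threshold=0.97).n_edges == 0


def test_threshold_bounds_rejected():
    r = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
    for bad in (-1.0, 1.5):
        with pytest.raises(ValueError):
            nm.build_network(r, threshold=bad)


def test_raising_threshold_never_adds_edges():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(15, 6))
    r = pd.DataFrame(np.corrcoef(x), index=[f"g{i}" for i in range(15)],
                     columns=[f"g{i}" for i in range(15)])
    loose = {tuple(sorted(e)) for e in nm.build_network(r, threshold=0.2).graph.edges}
    tight = {tuple(sorted(e)) for e in nm.build_network(r, threshold=0.6).graph.edges}
    assert tight <= loose


def _as_net(graph):
    return nm.CoexpressionNetwork(graph=graph, threshold=0.97, mode="positive")


def test_star_graph_degrees_and_hub():
    graph = nx.Graph([("c", f"l{i}") for i in range(4)])
    net = _as_net(graph)
    degrees = nm.node_degrees(net)
    assert degrees["c"] == 4 and all(degrees[f"l{i}"] == 1 for i in range(4))
    hubs = nm.identify_hubs(net, hub_k=1)
    assert hubs.hubs == ["c"]
    assert hubs.degree_range == (4, 4)


def test_empty_graph_degrees_zero():
    graph = nx.Graph()
    graph.add_nodes_from("abc")
    assert set(nm.node_degrees(_as_net(graph)).values()) == {0}


def test_degrees_equal_adjacency_row_sums():
    graph = nx.erdos_renyi_graph(30, 0.2, seed=3)
    graph = nx.relabel_nodes(graph, {i: f"g{i:02d}" for i in graph.nodes})
    net = _as_net(graph)
    degrees = nm.node_degrees(net)
    nodes = sorted(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    for i, node in enumerate(nodes):
        assert degrees[node] == adj[i].sum()


def test_hub_tie_break_is_lexicographic():
    graph = nx.cycle_graph(5)
    graph = nx.relabel_nodes(graph, {i: f"n{i}" for i in graph.nodes})
    hubs = nm.identify_hubs(_as_net(graph), hub_k=2)
    assert hubs.hubs == ["n0", "n1"]


def test_hub_degrees_match_sorted_top_k():
    graph = nx.erdos_renyi_graph(40, 0.3, seed=9)
    graph = nx.relabel_nodes(graph, {i: f"g{i:02d}" for i in graph.nodes})
    net = _as_net(graph)
    hubs = nm.identify_hubs(net, hub_k=10)
    degrees = sorted((d for _, d in graph.degree()), reverse=True)
    assert sorted((graph.degree(g) for g in hubs.hubs), reverse=True) == degrees[:10]


def test_hub_k_must_be_positive():
    with pytest.raises(ValueError):
        nm.identify_hubs(_as_net(nx.path_graph(3)), hub_k=0)


def test_components_triangle_plus_isolate():
    graph = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
    graph.add_node("z")
    comps, single = nm.connected_components(_as_net(graph))
    assert len(comps) == 2 and not single


def test_path_graph_is_single_component():
    graph = nx.relabel_nodes(nx.path_graph(6), {i: f"n{i}" for i in range(6)})
    comps, single = nm.connected_components(_as_net(graph))
    assert single and comps[0] == set(graph.nodes)


def test_components_match_union_find(default_dataset):
    matrix, design, _, table = default_dataset
    corr = nm.correlation_matrix(matrix, design, table.deg_genes)
    net = nm.build_network(corr.r)
    comps, _ = nm.connected_components(net)
    expected = union_find_components(list(net.graph.nodes), list(net.graph.edges))
    assert sorted(map(sorted, comps)) == sorted(map(sorted, expected))


def test_degree_sum_is_twice_edge_count(default_dataset):
    matrix, design, _, table = default_dataset
    corr = nm.correlation_matrix(matrix, design, table.deg_genes)
    net = nm.build_network(corr.r)
    assert sum(nm.node_degrees(net).values()) == 2 * net.n_edges


def test_absolute_mode_is_union_of_signed_networks():
    rng = np.random.default_rng(13)
    x = rng.normal(size=(12, 5))
    ids = [f"g{i}" for i in range(12)]
    r = pd.DataFrame(np.corrcoef(x), index=ids, columns=ids)
    pos = {tuple(sorted(e)) for e in nm.build_network(r, 0.3, "positive").graph.edges}
    neg = {tuple(sorted(e)) for e in nm.build_network(-r, 0.3, "positive").graph.edges}
    both = {tuple(sorted(e)) for e in nm.build_network(r, 0.3, "absolute").graph.edges}
    assert both == pos | neg


def test_region_partition_on_clean_templates():
    """Step profiles -> ER with earliness 1; log-time ramp -> LR with
    earliness log(3)/log(73); flat -> none."""
    times = [0, 2, 12, 24, 72]
    design = _design(times)
    t = np.asarray(times, dtype=float)
    step = 9.0 + np.where(t > 0, 4.0, 0.0)
    ramp = 9.0 + 4.0 * np.log1p(t) / np.log1p(t[-1])
    flat = np.full_like(t, 9.0)
    matrix = _matrix([step, ramp, flat], design, genes=["gs", "gr", "gf"])
    graph = nx.Graph()
    graph.add_nodes_from(["gs", "gr", "gf"])
    net = _as_net(graph)
    bins = {"gs": 0, "gr": 1, "gf": 2}
    regions, bin_label, bin_e = nm.partition_regions(net, bins, matrix, design)
    assert regions == {"gs": "ER", "gr": "LR", "gf": "none"}
    assert bin_e[0] == pytest.approx(1.0)
    assert bin_e[1] == pytest.approx(math.log(3) / math.log(73), abs=1e-12)
    assert bin_label == {0: "ER", 1: "LR", 2: "none"}


def test_region_partition_requires_assignment():
    graph = nx.Graph()
    graph.add_node("g0")
    design = _design([0, 2, 12])
    matrix = _matrix([[1, 2, 3]], design)
    with pytest.raises(ValueError, match="SOM"):
        nm.partition_regions(_as_net(graph), {}, matrix, design)
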