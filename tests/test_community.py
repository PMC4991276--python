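"""Threshold graph, modularity, Girvan-Newman partition, group statistics."""

from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from opto import (
    GridSpec,
    build_threshold_graph,
    girvan_newman_partition,
    group_stats,
    mean_random_pair_distance,
    modularity,
)
from opto.community import Partition


# --- independent oracle: exhaustive max-Q over all set partitions -----------


def _set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partial in _set_partitions(rest):
        for k in range(len(partial)):
            yield partial[:k] + [partial[k] + [first]] + partial[k + 1 :]
        yield [[first]] + partial


def _exact_modularity(G, parts):
    """Q in exact rational arithmetic."""
    m = G.number_of_edges()
    group_of = {v: g for g, part in enumerate(parts) for v in part}
    e_in = [0] * len(parts)
    ends = [0] * len(parts)
    for u, v in G.edges():
        ends[group_of[u]] += 1
        ends[group_of[v]] += 1
        if group_of[u] == group_of[v]:
            e_in[group_of[u]] += 1
    return sum(
        Fraction(e_in[g], m) - Fraction(ends[g], 2 * m) ** 2 for g in range(len(parts))
    )


def _brute_force_max_q(G):
    return max(
        _exact_modularity(G, parts) for parts in _set_partitions(sorted(G.nodes()))
    )


# --- threshold graph ---------------------------------------------------------


def test_threshold_is_strict():
    M = np.full((3, 3), 0.5)
    np.fill_diagonal(M, 0.0)
    assert build_threshold_graph(M).number_of_edges() == 0
    M2 = np.full((3, 3), 0.51)
    np.fill_diagonal(M2, 0.0)
    G = build_threshold_graph(M2)
    assert G.number_of_edges() == 3  # triangle


def test_threshold_graph_keeps_isolated_nodes():
    M = np.full((4, 4), 0.1)
    M[1, 2] = M[2, 1] = 0.9
    np.fill_diagonal(M, 0.0)
    G = build_threshold_graph(M)
    assert set(G.nodes()) == {0, 1, 2, 3}
    assert set(map(frozenset, G.edges())) == {frozenset({1, 2})}


def test_threshold_graph_rejects_asymmetric_matrix():
    M = np.full((3, 3), 0.4)
    M[0, 1] = 0.9
    with pytest.raises(ValueError):
        build_threshold_graph(M)


# --- modularity --------------------------------------------------------------


def _two_triangles():
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
    return G


def test_modularity_single_community_is_zero():
    G = _two_triangles()
    assert modularity(G, [list(G.nodes())]) == pytest.approx(0.0)


def test_modularity_two_disjoint_triangles():
    G = _two_triangles()
    assert modularity(G, [[0, 1, 2], [3, 4, 5]]) == pytest.approx(0.5)


def test_modularity_all_singletons():
    G = _two_triangles()
    assert modularity(G, [[v] for v in G.nodes()]) == pytest.approx(-1 / 6)


def test_modularity_undefined_without_edges():
    G = nx.empty_graph(4)
    with pytest.raises(ValueError):
        modularity(G, [[0, 1], [2, 3]])


def test_modularity_agrees_with_networkx():
    rng = np.random.default_rng(1)
    for _ in range(20):
        G = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0:
            continue
        parts = [
            list(c)
            for c in nx.community.label_propagation_communities(G)
        ]
        assert modularity(G, parts) == pytest.approx(
            nx.community.modularity(G, parts), abs=1e-12
        )


# --- Girvan-Newman partition -------------------------------------------------


def test_two_cliques_with_bridge_split_at_the_bridge():
    G = nx.Graph()
    for base in (0, 4):
        nodes = range(base, base + 4)
        G.add_edges_from((u, v) for u in nodes for v in nodes if u < v)
    G.add_edge(0, 4)
    part = girvan_newman_partition(G)
    assert set(part.groups) == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}
    assert part.modularity == pytest.approx(float(_brute_force_max_q(G)))


def test_single_triangle_is_one_group():
    G = nx.complete_graph(3)
    part = girvan_newman_partition(G)
    assert part.groups == (frozenset({0, 1, 2}),)
    assert part.modularity == pytest.approx(0.0)


def test_partition_q_not_below_single_group():
    rng = np.random.default_rng(2)
    for _ in range(10):
        G = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
        if G.number_of_edges() == 0:
            continue
        part = girvan_newman_partition(G)
        assert part.modularity >= -1e-12


def test_edgeless_graph_gives_singletons_with_undefined_q():
    part = girvan_newman_partition(nx.empty_graph(5))
    assert part.n_groups == 5
    assert part.modularity is None


def test_empty_graph_gives_empty_partition():
    part = girvan_newman_partition(nx.Graph())
    assert part.groups == ()


def test_disconnected_components_partitioned_independently():
    G = _two_triangles()
    part = girvan_newman_partition(G)
    assert set(part.groups) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
    assert part.modularity == pytest.approx(0.5)


def test_never_exceeds_exhaustive_max_q_and_q_is_consistent():
    """Edge-betweenness deletion is a heuristic: its deletion hierarchy need
    not contain the global max-Q partition, so on dense unstructured graphs it
    may fall short of the exhaustive optimum. The invariants that must hold on
    every graph are (a) the reported Q never exceeds the exhaustive maximum,
    (b) it equals the exactly recomputed modularity of the returned partition,
    and (c) it is at least the trivial one-group partition's Q of zero on a
    connected graph."""
    rng = np.random.default_rng(2024)
    checked = 0
    while checked < 50:
        n = int(rng.integers(4, 9))
        p = rng.uniform(0.3, 0.7)
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not nx.is_connected(G):
            continue
        checked += 1
        part = girvan_newman_partition(G)
        q_best = float(_brute_force_max_q(G))
        assert part.modularity <= q_best + 1e-9
        assert part.modularity >= -1e-12
        q_exact = _exact_modularity(G, [set(g) for g in part.groups])
        assert part.modularity == pytest.approx(float(q_exact), abs=1e-12)


def test_matches_exhaustive_max_q_on_planted_communities():
    """On graphs with clear community structure — cliques joined by single
    bridge edges — the deletion hierarchy does reach the global optimum."""
    rng = np.random.default_rng(77)
    done = 0
    while done < 15:
        sizes = rng.integers(3, 6, size=int(rng.integers(2, 4)))
        if sizes.sum() > 10:  # keep the Bell-number oracle tractable
            continue
        done += 1
        G = nx.Graph()
        offset = 0
        anchors = []
        for s in sizes:
            G = nx.compose(G, nx.relabel_nodes(nx.complete_graph(int(s)), {k: k + offset for k in range(int(s))}))
            anchors.append(offset)
            offset += int(s)
        for a, b in zip(anchors, anchors[1:]):
            G.add_edge(a, b)
        part = girvan_newman_partition(G)
        q_best = float(_brute_force_max_q(G))
        assert part.modularity == pytest.approx(q_best, abs=1e-9)


# --- group statistics --------------------------------------------------------


def _partition(*groups, q=0.1):
    return Partition(groups=tuple(frozenset(g) for g in groups), modularity=q)


def test_group_stats_adjacent_pair():
    grid = GridSpec(8, 8)
    part = _partition([grid.agent_at(0, 0), grid.agent_at(0, 1)])
    stats = group_stats(part, grid)
    assert stats.mean_within_group_distance == pytest.approx(1.0)
    assert stats.n_groups_nonsingleton == 1


def test_group_stats_excludes_singletons_from_distance():
    grid = GridSpec(8, 8)
    part = _partition(
        [grid.agent_at(0, 0), grid.agent_at(4, 4)], [grid.agent_at(1, 1)]
    )
    stats = group_stats(part, grid)
    assert stats.mean_within_group_distance == pytest.approx(8.0)
    assert stats.n_groups_all == 2
    assert stats.n_groups_nonsingleton == 1
    assert not stats.whole_network_flag


def test_group_stats_flags_whole_network():
    grid = GridSpec(4, 4)
    part = _partition(range(16))
    stats = group_stats(part, grid)
    assert stats.whole_network_flag
    assert stats.n_groups_all == 1


def test_group_stats_no_multimember_group_distance_undefined():
    grid = GridSpec(4, 4)
    part = _partition(*[[a] for a in range(16)])
    stats = group_stats(part, grid)
    assert stats.mean_within_group_distance is None
    assert stats.n_groups_nonsingleton == 0


def test_random_partition_distance_near_null_expectation():
    """Randomly assigned large groups have within-group distance near the
    independent-uniform null (exactly 4 on the 8x8 torus)."""
    grid = GridSpec(8, 8)
    rng = np.random.default_rng(3)
    means = []
    for _ in range(60):
        labels = rng.integers(0, 4, size=64)
        groups = [np.flatnonzero(labels == g).tolist() for g in range(4)]
        part = _partition(*[g for g in groups if g])
        means.append(group_stats(part, grid).mean_within_group_distance)
    assert np.mean(means) == pytest.approx(
        mean_random_pair_distance(grid), abs=0.1
    )
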