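"""Group extraction from the affinity network.

The final affinity matrix is binarised (two agents are connected when their
mutual affinity strictly exceeds a threshold, 0.5 by default) and the
modularity-maximising partition is found by Girvan–Newman edge-betweenness
deletion: the edge participating in the most shortest paths is removed,
betweenness is recomputed, and the connected-component partition is scored at
every step by the modularity Q of the ORIGINAL edge set; the partition with
the highest Q over the whole dendrogram is returned. Group statistics follow
the convention that singleton groups are excluded from group counts and from
the within-group distance, and a best partition that keeps the whole network
in one group is flagged and excluded from group-count aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .topology import GridSpec, torus_distance

__all__ = [
    "Partition",
    "GroupStats",
    "build_threshold_graph",
    "modularity",
    "girvan_newman_partition",
    "group_stats",
]


@dataclass(frozen=True)
class Partition:
    """A disjoint cover of all nodes by groups, with its modularity.

    ``modularity`` is None for an edgeless graph, where Q is undefined.
    """

    groups: tuple[frozenset, ...]
    modularity: Optional[float]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_of(self) -> dict:
        return {node: g for g, members in enumerate(self.groups) for node in members}


@dataclass(frozen=True)
class GroupStats:
    """Counts and spatial statistics of a partition on the grid."""

    n_groups_all: int
    n_groups_nonsingleton: int
    whole_network_flag: bool
    mean_within_group_distance: Optional[float]
    n_within_pairs: int = 0


def build_threshold_graph(
    affinities: np.ndarray, threshold: float = 0.5
) -> nx.Graph:
    """Unweighted graph with an edge wherever affinity strictly exceeds ``threshold``.

    All agents appear as nodes, so agents connected to no one are retained as
    isolated nodes.
    """
    affinities = np.asarray(affinities, dtype=float)
    n = affinities.shape[0]
    if affinities.shape != (n, n):
        raise ValueError("affinity matrix must be square")
    if not np.allclose(affinities, affinities.T):
        raise ValueError("affinity matrix must be symmetric")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(affinities > threshold, k=1))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    return G


def modularity(G: nx.Graph, communities: Sequence[Sequence]) -> float:
    """Newman–Girvan modularity Q = sum_g (e_gg - a_g^2).

    e_gg is the fraction of edges with both endpoints in group g and a_g the
    fraction of edge endpoints attached to g. Undefined (raises) on a graph
    with no edges.
    """
    m = G.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined for a graph with no edges")
    group_of = {node: g for g, members in enumerate(communities) for node in members}
    if len(group_of) != G.number_of_nodes():
        raise ValueError("partition must cover every node exactly once")
    n_groups = len(communities)
    e_within = np.zeros(n_groups)
    ends = np.zeros(n_groups)
    for u, v in G.edges():
        gu, gv = group_of[u], group_of[v]
        ends[gu] += 1
        ends[gv] += 1
        if gu == gv:
            e_within[gu] += 1
    return float(np.sum(e_within / m - (ends / (2 * m)) ** 2))


def _components(G: nx.Graph) -> tuple[frozenset, ...]:
    comps = [frozenset(c) for c in nx.connected_components(G)]
    return tuple(sorted(comps, key=min))


def girvan_newman_partition(G: nx.Graph) -> Partition:
    """Best-Q partition over the Girvan–Newman edge-deletion dendrogram.

    Edge betweenness is recomputed after every removal (exact, all-pairs
    shortest paths); betweenness ties are broken by lowest edge index so runs
    are deterministic. Q of the component partition is always evaluated
    against the original edge set, and the first partition attaining the
    maximum is kept (the dendrogram only refines, so this is also the
    coarsest). Disconnected inputs start from their component partition;
    isolated nodes form singleton groups. An edgeless graph yields the
    all-singleton partition with undefined modularity.
    """
    if G.number_of_nodes() == 0:
        return Partition(groups=(), modularity=None)
    if G.number_of_edges() == 0:
        return Partition(
            groups=tuple(frozenset([v]) for v in sorted(G.nodes())), modularity=None
        )

    work = G.copy()
    best = _components(work)
    best_q = modularity(G, best)
    while work.number_of_edges() > 0:
        betweenness = nx.edge_betweenness_centrality(work)
        target = max(
            betweenness,
            key=lambda e: (betweenness[e], (-min(e), -max(e))),
        )
        work.remove_edge(*target)
        comps = _components(work)
        q = modularity(G, comps)
        if q > best_q:
            best, best_q = comps, q
    return Partition(groups=best, modularity=best_q)


def group_stats(
    partition: Partition, grid: GridSpec, positions: Optional[np.ndarray] = None
) -> GroupStats:
    """Group counts and pooled within-group torus distance.

    The mean distance pools all unordered pairs inside groups of two or more
    members; singleton groups contribute nothing to it. ``positions`` defaults
    to the grid's agent-index order.
    """
    if positions is None:
        positions = grid.positions()
    n_nodes = sum(len(g) for g in partition.groups)
    whole = partition.n_groups == 1 and n_nodes > 1
    nonsingleton = [g for g in partition.groups if len(g) >= 2]
    total = 0.0
    pairs = 0
    for g in nonsingleton:
        members = sorted(g)
        for a_idx, a in enumerate(members):
            for b in members[a_idx + 1 :]:
                total += torus_distance(
                    tuple(positions[a]), tuple(positions[b]), grid
                )
                pairs += 1
    mean_dist = total / pairs if pairs else None
    return GroupStats(
        n_groups_all=partition.n_groups,
        n_groups_nonsingleton=len(nonsingleton),
        whole_network_flag=whole,
        mean_within_group_distance=mean_dist,
        n_within_pairs=pairs,
    )
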