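"""KNN graphs over distance matrices and the network comparison suite.

Graphs are built per node by k-nearest selection on the distance matrix
(union-symmetrized, so degrees can exceed k), with edge weights equal to the
distances, globally max-normalized.  Comparisons between two graphs on the
same genomes: Newman modularity of a partition, the Jaccard family over edge
sets, and DeltaCon — a similarity between the node-affinity matrices of the
two graphs obtained from linearized (fast) belief propagation,

    S = (I + eps^2 D - eps A)^{-1},

compared with the Matusita (root-Euclidean) distance
d = sqrt(sum_ij (sqrt(S1_ij) - sqrt(S2_ij))^2) and reported as
sim = 1 / (1 + d).  Node attribution is the per-row root-Euclidean distance;
edge attribution sums the endpoint attributions of every edge present in
exactly one graph, signed by addition (+) or removal (-).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import AlignmentError, DomainError
from .types import KnnGraphSpec, LabeledMatrix

__all__ = [
    "knn_graph",
    "modularity",
    "edge_set_similarities",
    "deltacon",
    "girvan_newman",
    "DeltaConReport",
    "GirvanNewmanResult",
    "write_edge_list",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# KNN construction
# ---------------------------------------------------------------------------

def knn_graph(d: LabeledMatrix, k: int) -> KnnGraphSpec:
    """Union-symmetrized k-nearest-neighbour graph of a distance matrix.

    Each node selects its k nearest other nodes (ties broken by label
    order); the union of directed selections forms the undirected edge set.
    Edge weights are the distances, then divided by the global maximum
    weight.  Independent of input row order given the same labels.
    """
    n = d.n
    if k < 1 or k >= n:
        raise DomainError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    v = d.values.copy()
    if d.zero_is_missing:
        off = ~np.eye(n, dtype=bool)
        v[(v == 0.0) & off] = 1.0
    v = (v + v.T) / 2.0
    edges: dict[tuple[str, str], float] = {}
    for i in range(n):
        order = np.lexsort((np.arange(n), v[i]))  # distance, then label order
        neighbours = [j for j in order if j != i][:k]
        for j in neighbours:
            a, b = (i, j) if i < j else (j, i)
            edges[(d.labels[a], d.labels[b])] = float(v[a, b])
    if edges:
        wmax = max(edges.values())
        if wmax > 0:
            edges = {e: w / wmax for e, w in edges.items()}
    return KnnGraphSpec(nodes=d.labels, edges=edges, k=k)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def _as_communities(
    nodes: Sequence[str], partition: Mapping[str, object] | Iterable[Iterable[str]]
) -> list[set[str]]:
    if isinstance(partition, Mapping):
        groups: dict[object, set[str]] = {}
        for node, com in partition.items():
            groups.setdefault(com, set()).add(node)
        communities = list(groups.values())
    else:
        communities = [set(c) for c in partition]
    covered = set().union(*communities) if communities else set()
    if covered != set(nodes):
        raise DomainError("partition does not cover all nodes exactly")
    return communities


def modularity(
    g: KnnGraphSpec,
    partition: Mapping[str, object] | Iterable[Iterable[str]],
    weighted: bool = False,
) -> float:
    """Newman modularity Q of a node partition (unweighted by default)."""
    communities = _as_communities(g.nodes, partition)
    graph = g.to_networkx(weighted=weighted)
    return float(
        nx.community.modularity(
            graph, communities, weight="weight" if weighted else None
        )
    )


# ---------------------------------------------------------------------------
# Edge-set similarities
# ---------------------------------------------------------------------------

def edge_set_similarities(
    g1: KnnGraphSpec, g2: KnnGraphSpec
) -> tuple[float, float, float]:
    """(jaccard, weighted_jaccard, dice) over the two edge sets.

    weighted_jaccard = sum_e min(w1, w2) / sum_e max(w1, w2) over the edge
    union, an absent edge contributing weight 0.  Two empty graphs compare
    as identical (1, 1, 1).
    """
    if set(g1.nodes) != set(g2.nodes):
        raise AlignmentError("graphs are over different node sets")
    e1, e2 = g1.edges, g2.edges
    union = set(e1) | set(e2)
    if not union:
        return (1.0, 1.0, 1.0)
    inter = set(e1) & set(e2)
    jaccard = len(inter) / len(union)
    dice = 2 * len(inter) / (len(e1) + len(e2)) if (e1 or e2) else 1.0
    mins = sum(min(e1.get(e, 0.0), e2.get(e, 0.0)) for e in union)
    maxs = sum(max(e1.get(e, 0.0), e2.get(e, 0.0)) for e in union)
    wj = mins / maxs if maxs > 0 else (1.0 if mins == maxs else 0.0)
    return (float(jaccard), float(wj), float(dice))


# ---------------------------------------------------------------------------
# DeltaCon
# ---------------------------------------------------------------------------

@dataclass
class DeltaConReport:
    epsilon: float
    distance: float
    similarity: float
    node_attribution: dict[str, float]
    edge_attribution: dict[tuple[str, str], float]


def _adjacency(g: KnnGraphSpec, weighted: bool) -> np.ndarray:
    pos = {u: i for i, u in enumerate(g.nodes)}
    a = np.zeros((len(g.nodes), len(g.nodes)))
    for (u, v), w in g.edges.items():
        val = w if weighted else 1.0
        a[pos[u], pos[v]] = a[pos[v], pos[u]] = val
    return a


def fabp_affinity(adjacency: np.ndarray, epsilon: float) -> np.ndarray:
    """Node-affinity matrix S = (I + eps^2 D - eps A)^{-1}."""
    deg = adjacency.sum(axis=1)
    n = adjacency.shape[0]
    m = np.eye(n) + epsilon**2 * np.diag(deg) - epsilon * adjacency
    try:
        s = np.linalg.solve(m, np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise DomainError(
            f"singular belief-propagation system at epsilon={epsilon}; retry smaller"
        ) from exc
    return s


def deltacon(
    g1: KnnGraphSpec,
    g2: KnnGraphSpec,
    epsilon: float | None = None,
    weighted: bool = False,
) -> DeltaConReport:
    """DeltaCon distance/similarity with node and edge attribution.

    ``epsilon`` defaults to 1 / (1 + max degree) over both graphs.  The
    default compares the unweighted adjacency of the KNN edge sets.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise AlignmentError("graphs are over different node sets")
    nodes = g1.nodes
    g2 = (
        g2
        if g2.nodes == nodes
        else KnnGraphSpec(
            nodes,
            {g1.canonical_edge(u, v): w for (u, v), w in g2.edges.items()},
            g2.k,
        )
    )
    a1 = _adjacency(g1, weighted)
    a2 = _adjacency(g2, weighted)
    if epsilon is None:
        max_deg = max(
            float(np.count_nonzero(a1, axis=1).max(initial=0)),
            float(np.count_nonzero(a2, axis=1).max(initial=0)),
        )
        epsilon = 1.0 / (1.0 + max_deg)
    s1 = np.clip(fabp_affinity(a1, epsilon), 0.0, None)
    s2 = np.clip(fabp_affinity(a2, epsilon), 0.0, None)
    diff = np.sqrt(s1) - np.sqrt(s2)
    distance = float(np.sqrt((diff**2).sum()))
    node_attr = {
        u: float(np.sqrt((diff[i] ** 2).sum())) for i, u in enumerate(nodes)
    }
    edge_attr: dict[tuple[str, str], float] = {}
    for e in set(g1.edges) ^ set(g2.edges):
        u, v = e
        impact = node_attr[u] + node_attr[v]
        edge_attr[e] = impact if e in g2.edges else -impact
    return DeltaConReport(
        epsilon=float(epsilon),
        distance=distance,
        similarity=1.0 / (1.0 + distance),
        node_attribution=node_attr,
        edge_attribution=edge_attr,
    )


# ---------------------------------------------------------------------------
# Girvan-Newman communities
# ---------------------------------------------------------------------------

@dataclass
class GirvanNewmanResult:
    """Split sequence (community dendrogram) and the max-modularity level."""

    levels: list[list[set[str]]]
    best_partition: list[set[str]]
    best_modularity: float


def girvan_newman(g: KnnGraphSpec) -> GirvanNewmanResult:
    """Iteratively remove the highest-betweenness edge; choose the split
    level with maximum (unweighted) modularity.

    Level 0 is the component partition of the input graph, so the chosen
    partition never scores below the trivial one-community Q = 0 on a
    connected graph.  An edgeless graph yields all-singleton communities.
    """
    graph = g.to_networkx(weighted=False)
    levels: list[list[set[str]]] = [
        [set(c) for c in nx.connected_components(graph)]
    ]
    if graph.number_of_edges() > 0:
        for split in nx.community.girvan_newman(graph):
            levels.append([set(c) for c in split])
    best_idx, best_q = 0, -np.inf
    for idx, level in enumerate(levels):
        if graph.number_of_edges() == 0:
            q = 0.0
        else:
            q = float(nx.community.modularity(graph, level, weight=None))
        if q > best_q + 1e-12:
            best_idx, best_q = idx, q
    return GirvanNewmanResult(
        levels=levels,
        best_partition=levels[best_idx],
        best_modularity=float(best_q),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_edge_list(path, g: KnnGraphSpec) -> None:
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for (u, v), w in sorted(g.edges.items()):
            fh.write(f"{u}\t{v}\t{format(w, '.12g')}\n")


def write_graphml(path, g: KnnGraphSpec) -> None:
    nx.write_graphml(g.to_networkx(weighted=True), path)
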