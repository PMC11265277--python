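"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the production code paths: explicit list rotations,
scalar cosine arithmetic via math.sqrt, statistics.mean/median, pairwise
loops.  They are the oracles the fast implementations are checked against.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

import numpy as np


def brute_force_synteny(
    order_a: list[str],
    order_b: list[str],
    pairs: list[tuple[str, str]],
    vector_mode: str = "genome-vectors",
    within: str = "mean",
) -> tuple[float, list[float]]:
    """Median synteny similarity by explicit enumeration of rotations."""

    def rotations() -> list[tuple[list[str], list[str]]]:
        arrs = [(list(order_a), list(order_b))]
        for ga, gb in pairs:
            ia, ib = order_a.index(ga), order_b.index(gb)
            arrs.append(
                (order_a[ia:] + order_a[:ia], order_b[ib:] + order_b[:ib])
            )
        return arrs

    scores = []
    for la, lb in rotations():
        rank_a = {g: i + 1 for i, g in enumerate(la)}
        rank_b = {g: i + 1 for i, g in enumerate(lb)}
        cosines = []
        for (a1, b1), (a2, b2) in combinations(pairs, 2):
            if vector_mode == "genome-vectors":
                u = (rank_a[a1], rank_a[a2])
                v = (rank_b[b1], rank_b[b2])
            else:
                u = (rank_a[a1], rank_b[b1])
                v = (rank_a[a2], rank_b[b2])
            dot = u[0] * v[0] + u[1] * v[1]
            cosines.append(
                dot
                / (
                    math.sqrt(u[0] ** 2 + u[1] ** 2)
                    * math.sqrt(v[0] ** 2 + v[1] ** 2)
                )
            )
        agg = statistics.mean if within == "mean" else statistics.median
        scores.append(agg(cosines))
    return statistics.median(scores), scores


def pairwise_silhouette(dist: np.ndarray, labels: list[int]) -> float:
    """Textbook silhouette: per-sample (b - a)/max(a, b), singletons 0."""
    n = len(labels)
    values = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            values.append(0.0)
            continue
        a = statistics.mean(dist[i][j] for j in same)
        b = math.inf
        for c in set(labels):
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, statistics.mean(dist[i][j] for j in other))
        denom = max(a, b)
        values.append(0.0 if denom == 0 else (b - a) / denom)
    return statistics.mean(values)


def pair_counting_rand(labels1: list[int], labels2: list[int]) -> float:
    """Rand index by explicit enumeration of all sample pairs."""
    n = len(labels1)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            together1 = labels1[i] == labels1[j]
            together2 = labels2[i] == labels2[j]
            agree += together1 == together2
            total += 1
    return agree / total if total else 1.0


def dense_inverse_affinity(adjacency: np.ndarray, epsilon: float) -> np.ndarray:
    """FaBP affinity by direct dense matrix inversion (the oracle route)."""
    deg = np.diag(adjacency.sum(axis=1))
    n = adjacency.shape[0]
    return np.linalg.inv(np.eye(n) + epsilon**2 * deg - epsilon * adjacency)


def naive_complete_linkage(dist: np.ndarray, n_clusters: int) -> list[int]:
    """Greedy agglomerative complete linkage with explicit cluster lists."""
    clusters: list[list[int]] = [[i] for i in range(len(dist))]
    while len(clusters) > n_clusters:
        best = None
        best_d = math.inf
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = max(dist[i][j] for i in clusters[x] for j in clusters[y])
                if d < best_d - 1e-15:
                    best_d = d
                    best = (x, y)
        x, y = best
        clusters[x] = clusters[x] + clusters[y]
        del clusters[y]
    labels = [0] * len(dist)
    for c, members in enumerate(clusters, start=1):
        for i in members:
            labels[i] = c
    return labels


def exact_kmer_jaccard(seq_a: str, seq_b: str, k: int) -> float:
    """Exact Jaccard of canonical k-mer sets (string arithmetic only)."""
    comp = str.maketrans("ACGT", "TGCA")

    def canon_set(s: str) -> set[str]:
        out = set()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k].upper()
            if set(kmer) - set("ACGT"):
                continue
            rc = kmer.translate(comp)[::-1]
            out.add(min(kmer, rc))
        return out

    sa, sb = canon_set(seq_a), canon_set(seq_b)
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)
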