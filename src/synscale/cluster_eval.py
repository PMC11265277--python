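"""Complete-linkage hierarchical clustering sweeps with silhouette and Rand
evaluation.

The cluster cutoff is the requested number of flat clusters (maxclust
criterion), varied over an integer axis.  Missing entries (zero with
``zero_is_missing``) are treated as the maximal distance 1 so that sparse
matrices still yield a complete dendrogram — that fill is a documented
choice, logged once per matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import rand_score as _sk_rand

from .errors import AlignmentError, DomainError
from .types import LabeledMatrix

logger = logging.getLogger(__name__)

MISSING_FILL_DISTANCE = 1.0


@dataclass
class ClusterSweep:
    labels: tuple[str, ...]
    cutoffs: list[int]
    labelings: dict[int, np.ndarray]
    silhouette: dict[int, float]  # NaN where undefined
    rand_vs_reference: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "silhouette": [self.silhouette[c] for c in self.cutoffs],
                "rand": [self.rand_vs_reference.get(c, np.nan) for c in self.cutoffs],
            }
        )


def _filled_distances(d: LabeledMatrix) -> np.ndarray:
    """Symmetric distance array with missing entries set to 1, zero diagonal."""
    v = d.values.copy()
    if d.zero_is_missing:
        off = ~np.eye(d.n, dtype=bool)
        n_missing = int(np.count_nonzero((v == 0.0) & off))
        if n_missing:
            logger.info(
                "clustering: filling %d missing distances with %.1f",
                n_missing,
                MISSING_FILL_DISTANCE,
            )
            v[(v == 0.0) & off] = MISSING_FILL_DISTANCE
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return v


def linkage_matrix(d: LabeledMatrix) -> np.ndarray:
    """Complete-linkage dendrogram of a distance matrix (scipy encoding)."""
    return hierarchy.linkage(squareform(_filled_distances(d), checks=False),
                             method="complete")


def hierarchical_labels(d: LabeledMatrix, n_clusters: int) -> np.ndarray:
    """Flat cluster labels (1..c) at the given cutoff, in label order."""
    if n_clusters < 1 or n_clusters > d.n:
        raise DomainError(f"n_clusters {n_clusters} outside 1..{d.n}")
    if n_clusters == d.n:
        return np.arange(1, d.n + 1)
    return hierarchy.fcluster(linkage_matrix(d), t=n_clusters, criterion="maxclust")


def silhouette_score(d: LabeledMatrix, labeling: Sequence[int]) -> float:
    """Mean silhouette (b - a) / max(a, b) over samples.

    Conventions: samples in singleton clusters score 0, and a sample with
    a = b = 0 (e.g. a zero distance matrix) scores 0.
    """
    labels = np.asarray(labeling)
    if labels.size != d.n:
        raise AlignmentError(f"{labels.size} labels for a {d.n}-genome matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DomainError("silhouette undefined for a single cluster")
    dist = _filled_distances(d)
    scores = np.zeros(d.n)
    for i in range(d.n):
        own = labels[i]
        mask_own = (labels == own) & (np.arange(d.n) != i)
        if not mask_own.any():  # singleton cluster
            scores[i] = 0.0
            continue
        a = dist[i, mask_own].mean()
        b = min(dist[i, labels == c].mean() for c in uniq if c != own)
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(scores.mean())


def rand_score(labeling_1: Sequence[int], labeling_2: Sequence[int]) -> float:
    """Plain (unadjusted) Rand index: agreeing pairs / C(n, 2)."""
    l1, l2 = np.asarray(labeling_1), np.asarray(labeling_2)
    if l1.size != l2.size:
        raise AlignmentError("labelings cover different genome sets")
    return float(_sk_rand(l1, l2))


def sweep(
    d: LabeledMatrix,
    reference: LabeledMatrix | Mapping[int, Sequence[int]] | None = None,
    cutoffs: Iterable[int] = range(1, 101),
) -> ClusterSweep:
    """Cluster at every cutoff; record silhouette and Rand vs the reference
    clustering at the same cutoff.

    ``reference`` is either another distance matrix (clustered the same way,
    e.g. the ANI matrix as ground-truth proxy) or a precomputed map
    cutoff -> labels.  Cutoffs above n are skipped; silhouette is NaN
    outside 2 <= c <= n - 1.
    """
    cutoffs = [c for c in cutoffs if 1 <= c <= d.n]
    Z = linkage_matrix(d)
    ref_Z = None
    if isinstance(reference, LabeledMatrix):
        if reference.labels != d.labels:
            raise AlignmentError("reference matrix labels differ")
        ref_Z = linkage_matrix(reference)

    labelings: dict[int, np.ndarray] = {}
    silh: dict[int, float] = {}
    rand: dict[int, float] = {}
    for c in cutoffs:
        labels = (
            np.arange(1, d.n + 1)
            if c == d.n
            else hierarchy.fcluster(Z, t=c, criterion="maxclust")
        )
        labelings[c] = labels
        if 2 <= len(np.unique(labels)) <= d.n - 1:
            silh[c] = silhouette_score(d, labels)
        else:
            silh[c] = float("nan")
        if ref_Z is not None:
            ref_labels = (
                np.arange(1, d.n + 1)
                if c == d.n
                else hierarchy.fcluster(ref_Z, t=c, criterion="maxclust")
            )
            rand[c] = rand_score(labels, ref_labels)
        elif reference is not None and c in reference:
            rand[c] = rand_score(labels, reference[c])
    return ClusterSweep(d.labels, cutoffs, labelings, silh, rand)


def to_newick(d: LabeledMatrix) -> str:
    """Newick export of the complete-linkage dendrogram (heights as branch
    lengths) for external tree viewers."""
    tree = hierarchy.to_tree(linkage_matrix(d))

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{d.labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"
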