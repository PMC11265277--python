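"""Core in-memory containers.

The universal currency between modules is :class:`LabeledMatrix`, a square
pairwise matrix (similarity, distance, ANI, covariance or augmented) carrying
genome labels.  Gene-level inputs are :class:`GeneFeature` /
:class:`GeneOrder`, and cross-genome orthology is an :class:`OrthologSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, DimensionError, DomainError

MATRIX_KINDS = ("similarity", "distance", "ani", "covariance", "augmented")

#: kinds whose present entries must lie in [0, 1]
_UNIT_RANGE_KINDS = ("similarity", "distance", "augmented")


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene (CDS or rRNA) from one genome.

    Coordinates are 1-based inclusive, GenBank style.  Strand is recorded but
    never used by the synteny measure.
    """

    genome_id: str
    replicon_index: int
    feature_index: int
    gene_id: str
    gene_name: str = ""
    product_description: str = ""
    start_bp: int = 1
    end_bp: int = 1
    strand: str = "+"
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise DomainError(
                f"gene {self.gene_id}: end_bp {self.end_bp} < start_bp {self.start_bp}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class GeneOrder:
    """A genome as a relatively ordered set of gene identifiers.

    This is the linear backbone of the pair synteny graph; ``rank`` of a gene
    is its 1-based index in ``ordered_gene_ids``.
    """

    genome_id: str
    ordered_gene_ids: tuple[str, ...]
    genome_length_bp: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_gene_ids", tuple(self.ordered_gene_ids))
        if len(set(self.ordered_gene_ids)) != len(self.ordered_gene_ids):
            raise DomainError(f"genome {self.genome_id}: duplicate gene_id in order")
        if self.genome_length_bp < 1:
            raise DomainError(f"genome {self.genome_id}: genome_length_bp < 1")

    def __len__(self) -> int:
        return len(self.ordered_gene_ids)

    def ranks(self) -> dict[str, int]:
        """1-based rank of every gene."""
        return {g: i + 1 for i, g in enumerate(self.ordered_gene_ids)}


@dataclass(frozen=True)
class OrthologHit:
    """One row of a BLAST-outfmt-6-like hit table."""

    query_gene_id: str
    subject_gene_id: str
    identity_pct: float
    aligned_length_bp: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise DomainError(f"identity_pct {self.identity_pct} outside [0, 100]")
        if self.aligned_length_bp < 1:
            raise DomainError("aligned_length_bp must be >= 1")


@dataclass
class OrthologSet:
    """Orthologous gene pairs linking two genomes (the cross edges of the
    pair synteny graph)."""

    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str]]
    identity_pct: list[float] | None = None
    aligned_length_bp: list[int] | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def swapped(self) -> "OrthologSet":
        """Same orthology viewed from genome B's side."""
        return OrthologSet(
            genome_a=self.genome_b,
            genome_b=self.genome_a,
            pairs=[(b, a) for a, b in self.pairs],
            identity_pct=None if self.identity_pct is None else list(self.identity_pct),
            aligned_length_bp=(
                None if self.aligned_length_bp is None else list(self.aligned_length_bp)
            ),
        )

    def is_one_to_one(self) -> bool:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        return len(set(a_side)) == len(a_side) and len(set(b_side)) == len(b_side)


class LabeledMatrix:
    """Square pairwise matrix with genome labels.

    Parameters
    ----------
    labels:
        Unique genome identifiers; row and column order both follow it.
    values:
        Square array of floats.
    kind:
        One of ``similarity``, ``distance``, ``ani``, ``covariance``,
        ``augmented``.  Unit-interval kinds are range-checked.
    zero_is_missing:
        If true, a zero entry encodes "no data" rather than the value 0
        (the sparse-matrix convention used throughout).
    """

    def __init__(
        self,
        labels: Sequence[str],
        values: np.ndarray,
        kind: str,
        zero_is_missing: bool = False,
        validate: bool = True,
    ) -> None:
        self.labels: tuple[str, ...] = tuple(str(x) for x in labels)
        self.values: np.ndarray = np.asarray(values, dtype=float)
        self.kind = kind
        self.zero_is_missing = bool(zero_is_missing)
        if validate:
            self._validate()

    def _validate(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise DomainError(f"unknown matrix kind {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise DimensionError(f"matrix is not square: shape {self.values.shape}")
        if len(self.labels) != self.values.shape[0]:
            raise DimensionError(
                f"{len(self.labels)} labels for a {self.values.shape[0]}-row matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise DomainError("duplicate labels")
        if self.kind in _UNIT_RANGE_KINDS:
            lo, hi = float(self.values.min(initial=0.0)), float(self.values.max(initial=0.0))
            if lo < -1e-12 or hi > 1.0 + 1e-12:
                raise DomainError(
                    f"{self.kind} matrix entries outside [0, 1]: min {lo}, max {hi}"
                )

    # -- basic protocol -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledMatrix):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.kind == other.kind
            and self.zero_is_missing == other.zero_is_missing
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return f"LabeledMatrix(n={self.n}, kind={self.kind!r})"

    # -- helpers ------------------------------------------------------------

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, rtol=0.0))

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise AlignmentError(f"label {label!r} not in matrix") from None

    def reindex(self, labels: Sequence[str]) -> "LabeledMatrix":
        """Return a copy with rows/columns reordered to ``labels``."""
        idx = [self.index_of(l) for l in labels]
        return LabeledMatrix(
            labels, self.values[np.ix_(idx, idx)], self.kind, self.zero_is_missing
        )

    def with_values(self, values: np.ndarray, kind: str | None = None,
                    zero_is_missing: bool | None = None) -> "LabeledMatrix":
        return LabeledMatrix(
            self.labels,
            values,
            self.kind if kind is None else kind,
            self.zero_is_missing if zero_is_missing is None else zero_is_missing,
        )

    def copy(self) -> "LabeledMatrix":
        return self.with_values(self.values.copy())


@dataclass(frozen=True)
class SketchProfile:
    """Bottom-s MinHash sketch of one genome or gene set."""

    kmer_size: int
    sketch_size: int
    hash_seed: int
    min_hashes: np.ndarray  # sorted ascending, unique, dtype uint64

    def __post_init__(self) -> None:
        h = np.asarray(self.min_hashes, dtype=np.uint64)
        object.__setattr__(self, "min_hashes", h)
        if h.size > 1 and not np.all(h[1:] > h[:-1]):
            raise DomainError("min_hashes must be sorted ascending with no duplicates")
        if h.size > self.sketch_size:
            raise DomainError("sketch larger than sketch_size")


@dataclass
class KnnGraphSpec:
    """Weighted undirected k-nearest-neighbour graph over genomes.

    Edges are stored once, keyed ``(u, v)`` with u before v in node order;
    weights are distances, globally max-normalized to [0, 1].
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float]
    k: int
    weight_semantics: str = "distance"

    def __post_init__(self) -> None:
        pos = {u: i for i, u in enumerate(self.nodes)}
        for (u, v), w in self.edges.items():
            if u == v:
                raise DomainError(f"self-loop on {u}")
            if pos[u] >= pos[v]:
                raise DomainError(f"edge ({u}, {v}) not in canonical node order")
            if w < 0:
                raise DomainError(f"negative edge weight on ({u}, {v})")

    def canonical_edge(self, u: str, v: str) -> tuple[str, str]:
        pos = {x: i for i, x in enumerate(self.nodes)}
        return (u, v) if pos[u] < pos[v] else (v, u)

    def degree(self, u: str) -> int:
        return sum(1 for (a, b) in self.edges if u in (a, b))

    def to_networkx(self, weighted: bool = True):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in self.edges.items():
            if weighted:
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
        return g


def require_same_labels(a: LabeledMatrix, b: LabeledMatrix) -> None:
    """Raise AlignmentError unless both matrices share labels and order."""
    if a.labels != b.labels:
        raise AlignmentError(
            "label mismatch: matrices must be reindexed to a common label order"
        )
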