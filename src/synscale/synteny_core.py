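"""The pair synteny graph and its similarity measure.

Two genomes are modelled as linear graphs of their gene orders, joined by
edges between orthologous gene pairs.  Because bacterial chromosomes are
circular, the given order is only one of many equivalent readings: for every
ortholog pair an extra *pivot arrangement* is formed by circularly rotating
both genomes so that the pivot pair's genes sit at rank 1, all other genes
keeping their cyclic order.

Within an arrangement, every unordered combination of two ortholog pairs
{i, j} contributes one cosine similarity between the position vectors

    u = (rank_A(i), rank_A(j)),   v = (rank_B(i), rank_B(j))

and the arrangement's score is the mean (configurably the median) of all
C(n, 2) cosines.  The final synteny similarity of the genome pair is the
median score across the 1 + n arrangements; the median damps the skew of the
original-order score, which is an arbitrary rotation of a circular genome.

Ranks are 1-based positions over the full gene order by default, so the
cosine arguments are always strictly positive and every score lies in
(0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlignmentError, DomainError, InsufficientOrthologsError
from .types import GeneOrder, LabeledMatrix, OrthologSet

VECTOR_MODES = ("genome-vectors", "ortholog-vectors")
WITHIN_STATS = ("mean", "median")
RANK_BASES = ("all", "orthologs")


@dataclass(frozen=True)
class SyntenyConfig:
    """Knobs of the measure.

    vector_mode:
        ``genome-vectors`` (default) pairs within-arrangement position
        vectors across genomes: u = (rank_A(i), rank_A(j)) vs
        v = (rank_B(i), rank_B(j)).  ``ortholog-vectors`` instead compares
        per-ortholog vectors u = (rank_A(i), rank_B(i)) vs
        v = (rank_A(j), rank_B(j)).
    within_arrangement:
        statistic over the C(n,2) cosines of one arrangement; default mean.
    rank_basis:
        ``all`` ranks genes over the full gene order; ``orthologs`` restricts
        ranking to orthologous genes only.
    """

    vector_mode: str = "genome-vectors"
    within_arrangement: str = "mean"
    rank_basis: str = "all"

    def __post_init__(self) -> None:
        if self.vector_mode not in VECTOR_MODES:
            raise DomainError(f"unknown vector_mode {self.vector_mode!r}")
        if self.within_arrangement not in WITHIN_STATS:
            raise DomainError(
                f"unknown within_arrangement {self.within_arrangement!r}"
            )
        if self.rank_basis not in RANK_BASES:
            raise DomainError(f"unknown rank_basis {self.rank_basis!r}")


@dataclass
class Arrangement:
    """One reading of the circular gene orders.

    ``pivot`` is "original" for the flat-file order, or the index of the
    ortholog pair whose genes were rotated to rank 1 in both genomes.
    """

    pivot: str | int
    rank_a: dict[str, int]
    rank_b: dict[str, int]


@dataclass
class SyntenyResult:
    similarity: float
    per_arrangement_scores: list[float]
    n_arrangements: int
    n_ortholog_pairs: int


# ---------------------------------------------------------------------------
# Ortholog canonicalization
# ---------------------------------------------------------------------------

def canonicalize_orthologs(orthologs: OrthologSet) -> OrthologSet:
    """Reduce many-to-many hits to a one-to-one mapping.

    Greedy by best identity; ties prefer the longer alignment, then
    lexicographic (gene_a, gene_b).  Pairs without identity metadata keep
    their input order.
    """
    n = len(orthologs.pairs)
    idx = list(range(n))
    ident = orthologs.identity_pct or [100.0] * n
    length = orthologs.aligned_length_bp or [0] * n
    idx.sort(
        key=lambda i: (
            -ident[i],
            -length[i],
            orthologs.pairs[i][0],
            orthologs.pairs[i][1],
        )
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    keep: list[int] = []
    for i in idx:
        a, b = orthologs.pairs[i]
        if a in used_a or b in used_b:
            continue
        used_a.add(a)
        used_b.add(b)
        keep.append(i)
    keep.sort()
    return OrthologSet(
        genome_a=orthologs.genome_a,
        genome_b=orthologs.genome_b,
        pairs=[orthologs.pairs[i] for i in keep],
        identity_pct=[ident[i] for i in keep] if orthologs.identity_pct else None,
        aligned_length_bp=(
            [length[i] for i in keep] if orthologs.aligned_length_bp else None
        ),
    )


# ---------------------------------------------------------------------------
# Arrangements
# ---------------------------------------------------------------------------

def _rotated_ranks(order: Sequence[str], pivot_gene: str) -> dict[str, int]:
    """Ranks after circularly rotating ``order`` so pivot_gene is rank 1."""
    i = order.index(pivot_gene)
    n = len(order)
    return {g: ((j - i) % n) + 1 for j, g in enumerate(order)}


def _base_orders(
    order_a: GeneOrder, order_b: GeneOrder, orthologs: OrthologSet, config: SyntenyConfig
) -> tuple[list[str], list[str]]:
    if config.rank_basis == "orthologs":
        in_a = {a for a, _ in orthologs.pairs}
        in_b = {b for _, b in orthologs.pairs}
        return (
            [g for g in order_a.ordered_gene_ids if g in in_a],
            [g for g in order_b.ordered_gene_ids if g in in_b],
        )
    return list(order_a.ordered_gene_ids), list(order_b.ordered_gene_ids)


def build_arrangements(
    order_a: GeneOrder,
    order_b: GeneOrder,
    orthologs: OrthologSet,
    config: SyntenyConfig = SyntenyConfig(),
) -> list[Arrangement]:
    """The original arrangement plus one pivot arrangement per ortholog pair.

    Requires a one-to-one ortholog set with at least two pairs; every gene in
    it must be resolvable in the corresponding gene order.
    """
    if len(orthologs.pairs) < 2:
        raise InsufficientOrthologsError(
            f"{orthologs.genome_a} vs {orthologs.genome_b}: "
            f"{len(orthologs.pairs)} ortholog pairs (need >= 2)"
        )
    if not orthologs.is_one_to_one():
        raise DomainError("ortholog set is not one-to-one; canonicalize first")
    set_a = set(order_a.ordered_gene_ids)
    set_b = set(order_b.ordered_gene_ids)
    for a, b in orthologs.pairs:
        if a not in set_a:
            raise AlignmentError(f"gene {a!r} not in genome {order_a.genome_id}")
        if b not in set_b:
            raise AlignmentError(f"gene {b!r} not in genome {order_b.genome_id}")

    base_a, base_b = _base_orders(order_a, order_b, orthologs, config)
    arrangements = [
        Arrangement(
            pivot="original",
            rank_a={g: i + 1 for i, g in enumerate(base_a)},
            rank_b={g: i + 1 for i, g in enumerate(base_b)},
        )
    ]
    for p, (ga, gb) in enumerate(orthologs.pairs):
        arrangements.append(
            Arrangement(
                pivot=p,
                rank_a=_rotated_ranks(base_a, ga),
                rank_b=_rotated_ranks(base_b, gb),
            )
        )
    return arrangements


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def arrangement_score(
    arr: Arrangement,
    orthologs: OrthologSet,
    config: SyntenyConfig = SyntenyConfig(),
) -> float:
    """Aggregate cosine similarity of one arrangement, in (0, 1]."""
    ra = np.array([arr.rank_a[a] for a, _ in orthologs.pairs], dtype=float)
    rb = np.array([arr.rank_b[b] for _, b in orthologs.pairs], dtype=float)
    n = ra.size
    if n < 2:
        raise InsufficientOrthologsError("arrangement_score needs >= 2 ortholog pairs")
    i, j = np.triu_indices(n, k=1)
    if config.vector_mode == "genome-vectors":
        # u = (rank_A(i), rank_A(j)), v = (rank_B(i), rank_B(j))
        dots = ra[i] * rb[i] + ra[j] * rb[j]
        sq_u = ra[i] ** 2 + ra[j] ** 2
        sq_v = rb[i] ** 2 + rb[j] ** 2
    else:
        # u = (rank_A(i), rank_B(i)), v = (rank_A(j), rank_B(j))
        dots = ra[i] * ra[j] + rb[i] * rb[j]
        sq_u = ra[i] ** 2 + rb[i] ** 2
        sq_v = ra[j] ** 2 + rb[j] ** 2
    # single sqrt keeps cosine(u, u) exactly 1
    cosines = dots / np.sqrt(sq_u * sq_v)
    stat = np.mean if config.within_arrangement == "mean" else np.median
    return float(min(stat(cosines), 1.0))


def synteny_similarity(
    order_a: GeneOrder,
    order_b: GeneOrder,
    orthologs: OrthologSet,
    config: SyntenyConfig = SyntenyConfig(),
    canonicalize: bool = True,
) -> SyntenyResult:
    """Median per-arrangement score across all 1 + n arrangements."""
    if canonicalize:
        orthologs = canonicalize_orthologs(orthologs)
    arrangements = build_arrangements(order_a, order_b, orthologs, config)
    scores = [arrangement_score(arr, orthologs, config) for arr in arrangements]
    return SyntenyResult(
        similarity=float(np.median(scores)),
        per_arrangement_scores=scores,
        n_arrangements=len(arrangements),
        n_ortholog_pairs=len(orthologs.pairs),
    )


def synteny_matrix(
    orders: Mapping[str, GeneOrder],
    ortholog_sets: Iterable[OrthologSet],
    config: SyntenyConfig = SyntenyConfig(),
) -> LabeledMatrix:
    """Pairwise similarity matrix over a corpus.

    The diagonal is 1; genome pairs lacking at least two ortholog pairs stay
    0 with ``zero_is_missing=True`` (the sparse-matrix convention).
    """
    labels = list(orders)
    if len(labels) < 2:
        raise DomainError("synteny_matrix requires >= 2 genomes")
    pos = {g: i for i, g in enumerate(labels)}
    values = np.zeros((len(labels), len(labels)), dtype=float)
    np.fill_diagonal(values, 1.0)
    for oset in ortholog_sets:
        if oset.genome_a not in pos or oset.genome_b not in pos:
            raise AlignmentError(
                f"ortholog set {oset.genome_a}/{oset.genome_b} references "
                "a genome absent from the corpus"
            )
        try:
            res = synteny_similarity(
                orders[oset.genome_a], orders[oset.genome_b], oset, config
            )
        except InsufficientOrthologsError:
            continue
        i, j = pos[oset.genome_a], pos[oset.genome_b]
        values[i, j] = values[j, i] = res.similarity
    return LabeledMatrix(labels, values, kind="similarity", zero_is_missing=True)


# ---------------------------------------------------------------------------
# Synteny coverage
# ---------------------------------------------------------------------------

def synteny_coverage(
    order: GeneOrder,
    orthologs: OrthologSet,
    which: str = "a",
    gene_intervals: Mapping[str, tuple[int, int]] | None = None,
) -> float:
    """Fraction of the chosen genome covered by shared ortholog blocks.

    Asymmetric: the summed shared-block length is divided by the total length
    of the chosen genome (``which`` selects side ``a`` or ``b`` of the
    ortholog set, which must correspond to ``order``).  When
    ``gene_intervals`` supplies 1-based inclusive (start, end) coordinates,
    physically overlapping blocks are merged so a fully tiled genome gives
    exactly 1; otherwise aligned block lengths are summed as-is.
    """
    if which not in ("a", "b"):
        raise DomainError(f"which must be 'a' or 'b', got {which!r}")
    if order.genome_length_bp <= 0:
        raise DomainError("genome length must be positive")
    genes = [p[0] if which == "a" else p[1] for p in orthologs.pairs]
    if not genes:
        return 0.0
    if gene_intervals is not None:
        ivals = sorted(gene_intervals[g] for g in genes)
        total = 0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    else:
        if orthologs.aligned_length_bp is None:
            raise DomainError(
                "coverage needs aligned block lengths or gene_intervals"
            )
        total = sum(orthologs.aligned_length_bp)
    return min(total / order.genome_length_bp, 1.0)
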