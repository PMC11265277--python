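"""MinHash genome sketching and Mash-style distances.

A bottom-s sketch keeps the s smallest 64-bit hash values over the canonical
k-mers of a sequence set.  The Jaccard index between two sketches is
estimated from the merged bottom sketch, and converted to a mutation-rate
distance with

    d = -(1/k) * ln(2j / (1 + j))

which is 0 at j = 1 and is clamped to 1 when j = 0 (the formula diverges).
Defaults k = 21, s = 1000.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptySketchError, MissingDataError, ParameterError
from .types import LabeledMatrix, SketchProfile

DEFAULT_KMER_SIZE = 21
DEFAULT_SKETCH_SIZE = 1000

_ENC = np.full(256, 255, dtype=np.uint8)
for _ch, _code in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
    _ENC[ord(_ch)] = _code
    _ENC[ord(_ch.lower())] = _code

_U64 = np.uint64


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64-style finalizer over uint64 values (vectorized)."""
    with np.errstate(over="ignore"):
        z = x + _U64((seed * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        return z ^ (z >> _U64(31))


def _canonical_kmer_hashes(seq: str, k: int, seed: int) -> np.ndarray:
    """Hashes of all canonical k-mers of ``seq`` (k-mers containing N skipped)."""
    enc = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = enc.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid_char = enc < 4
    # window valid iff all k characters valid
    cs = np.concatenate(([0], np.cumsum(valid_char)))
    window_valid = (cs[k:] - cs[:-k]) == k
    if k <= 31:
        e = enc.astype(np.uint64)
        e[~valid_char] = 0
        codes = np.zeros(n - k + 1, dtype=np.uint64)
        for t in range(k):
            codes = (codes << _U64(2)) | e[t : t + n - k + 1]
        # reverse complement: codes of the revcomp sequence, window-aligned
        e_rc = (_U64(3) - e)[::-1]
        rc_codes = np.zeros(n - k + 1, dtype=np.uint64)
        for t in range(k):
            rc_codes = (rc_codes << _U64(2)) | e_rc[t : t + n - k + 1]
        rc_codes = rc_codes[::-1]
        canon = np.minimum(codes, rc_codes)[window_valid]
        return _mix64(canon, seed)
    # long k-mers: keyed blake2b per window (slow path, rarely used)
    comp = str.maketrans("ACGT", "TGCA")
    key = int(seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
    hashes = []
    s = seq.upper()
    for i in np.nonzero(window_valid)[0]:
        kmer = s[i : i + k]
        rc = kmer.translate(comp)[::-1]
        canon = min(kmer, rc)
        h = hashlib.blake2b(canon.encode(), digest_size=8, key=key).digest()
        hashes.append(int.from_bytes(h, "little"))
    return np.array(hashes, dtype=np.uint64)


def sketch(
    sequences: str | Iterable[str],
    kmer_size: int = DEFAULT_KMER_SIZE,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 42,
) -> SketchProfile:
    """Bottom-s MinHash sketch of one sequence or a set of sequences.

    Deterministic for a fixed ``hash_seed``; canonical k-mers make the sketch
    strand-independent: ``sketch(s) == sketch(reverse_complement(s))``.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    parts = [_canonical_kmer_hashes(s, kmer_size, hash_seed) for s in sequences]
    allh = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    if allh.size == 0:
        raise EmptySketchError(
            f"no k-mers of size {kmer_size} (all sequences too short or all-N)"
        )
    uniq = np.unique(allh)  # sorted ascending
    return SketchProfile(kmer_size, sketch_size, hash_seed, uniq[:sketch_size])


def jaccard_estimate(a: SketchProfile, b: SketchProfile) -> float:
    """Jaccard index estimated from the merged bottom sketch.

    Exact when both sequence sets have <= sketch_size distinct k-mers.
    """
    _check_compatible(a, b)
    s = min(a.sketch_size, b.sketch_size)
    union = np.union1d(a.min_hashes, b.min_hashes)[:s]
    if union.size == 0:
        return 0.0
    shared = np.intersect1d(
        np.intersect1d(union, a.min_hashes, assume_unique=True),
        b.min_hashes,
        assume_unique=True,
    ).size
    return shared / union.size


def _check_compatible(a: SketchProfile, b: SketchProfile) -> None:
    if a.kmer_size != b.kmer_size:
        raise ParameterError(
            f"k-mer size mismatch: {a.kmer_size} vs {b.kmer_size}"
        )
    if a.hash_seed != b.hash_seed:
        raise ParameterError(f"hash seed mismatch: {a.hash_seed} vs {b.hash_seed}")


def mash_distance(a: SketchProfile, b: SketchProfile) -> float:
    """Mutation-rate distance between two sketches, in [0, 1]."""
    _check_compatible(a, b)
    j = jaccard_estimate(a, b)
    if j <= 0.0:
        return 1.0
    if j >= 1.0:
        return 0.0
    d = -np.log(2.0 * j / (1.0 + j)) / a.kmer_size
    return float(min(max(d, 0.0), 1.0))


def gene_set_distance(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    kmer_size: int = DEFAULT_KMER_SIZE,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 42,
    aggregation: str = "mean",
) -> float:
    """Distance between two gene sets (e.g. the 16S copies of two genomes).

    Every cross pair (one gene from each set) is sketched and compared; the
    per-pair distances are aggregated by ``mean`` (default) or ``min``.
    """
    if not genes_a or not genes_b:
        raise MissingDataError("gene_set_distance requires two non-empty gene sets")
    if aggregation not in ("mean", "min"):
        raise ParameterError(f"unknown aggregation {aggregation!r}")
    sk_a = [sketch(g, kmer_size, sketch_size, hash_seed) for g in genes_a]
    sk_b = [sketch(g, kmer_size, sketch_size, hash_seed) for g in genes_b]
    dists = [mash_distance(x, y) for x in sk_a for y in sk_b]
    return float(np.mean(dists) if aggregation == "mean" else np.min(dists))


def distance_matrix(
    genomes: Mapping[str, Sequence[str]],
    kmer_size: int = DEFAULT_KMER_SIZE,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    hash_seed: int = 42,
    aggregation: str = "mean",
    pooled: bool = False,
) -> LabeledMatrix:
    """Pairwise sketch-distance matrix over genomes.

    ``genomes`` maps genome_id to its list of sequences.  With
    ``pooled=False`` (the 16S-gene-set mode) distances aggregate over all
    cross pairs of sequences; with ``pooled=True`` each genome's sequences
    are pooled into a single sketch (the whole-genome mode, where a genome's
    replicons belong to one k-mer set).
    """
    labels = list(genomes)
    if len(labels) < 2:
        raise MissingDataError("distance_matrix requires >= 2 genomes")
    n = len(labels)
    values = np.zeros((n, n), dtype=float)
    if pooled:
        sketches = {
            g: sketch(genomes[g], kmer_size, sketch_size, hash_seed) for g in labels
        }
        for i in range(n):
            for j in range(i + 1, n):
                d = mash_distance(sketches[labels[i]], sketches[labels[j]])
                values[i, j] = values[j, i] = d
    else:
        if aggregation not in ("mean", "min"):
            raise ParameterError(f"unknown aggregation {aggregation!r}")
        per_gene = {}
        for g in labels:
            if not genomes[g]:
                raise MissingDataError(f"genome {g!r} has no sequences")
            per_gene[g] = [sketch(s, kmer_size, sketch_size, hash_seed) for s in genomes[g]]
        for i in range(n):
            for j in range(i + 1, n):
                dists = [
                    mash_distance(x, y)
                    for x in per_gene[labels[i]]
                    for y in per_gene[labels[j]]
                ]
                d = float(np.mean(dists) if aggregation == "mean" else np.min(dists))
                values[i, j] = values[j, i] = d
    return LabeledMatrix(labels, values, kind="distance")
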