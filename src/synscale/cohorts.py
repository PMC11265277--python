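"""Functional gene cohort construction.

Cohorts (core genes, antibiotic resistance, virulence, metabolic, mobile
genetic elements) share two filtering stages: a database-match identity
filter (> 90% by default) and the ortholog filter (> 95% identity, aligned
length between 500 and 2,500 bp inclusive, no self or within-genome hits).
Mobile genetic elements are flagged by case-insensitive keyword substring
match against product descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DomainError
from .types import GeneFeature, OrthologHit, OrthologSet

#: keywords identifying mobile-genetic-element products in flat-file
#: descriptions (plain substring, so "transposase-like" matches too)
DEFAULT_MGE_KEYWORDS = (
    "transposase",
    "transposon",
    "conjugative",
    "integrase",
    "integron",
    "recombinase",
    "conjugal",
    "mobilization",
    "recombination",
    "plasmid",
)


@dataclass(frozen=True)
class CohortSpec:
    name: str = "COR"
    db_identity_threshold_pct: float = 90.0
    ortholog_identity_threshold_pct: float = 95.0
    min_len_bp: int = 500
    max_len_bp: int = 2500
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_len_bp > self.max_len_bp:
            raise DomainError("min_len_bp > max_len_bp")
        for t in (self.db_identity_threshold_pct, self.ortholog_identity_threshold_pct):
            if not 0 <= t <= 100:
                raise DomainError(f"threshold {t} outside [0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "keywords" in data:
            data["keywords"] = tuple(data["keywords"])
        return cls(**data)


def flag_mge(
    features: Iterable[GeneFeature],
    keywords: Sequence[str] = DEFAULT_MGE_KEYWORDS,
) -> list[GeneFeature]:
    """Features whose product description contains any keyword
    (case-insensitive substring match)."""
    kws = [k.lower() for k in keywords]
    return [
        f
        for f in features
        if any(k in f.product_description.lower() for k in kws)
    ]


def filter_db_hits(
    hits: Iterable[OrthologHit], threshold_pct: float = 90.0
) -> list[OrthologHit]:
    """Database-match filter: keep hits with identity strictly above the
    threshold."""
    return [h for h in hits if h.identity_pct > threshold_pct]


def filter_orthologs(
    hits: Iterable[OrthologHit],
    spec: CohortSpec = CohortSpec(),
    gene_to_genome: Mapping[str, str] | None = None,
) -> list[OrthologHit]:
    """Ortholog filter shared by all cohorts.

    Keeps hits with identity strictly above the ortholog threshold and
    aligned length within [min_len_bp, max_len_bp] inclusive.  Self hits are
    always dropped; within-genome hits are dropped when ``gene_to_genome``
    is provided.  Idempotent.
    """
    out = []
    for h in hits:
        if h.query_gene_id == h.subject_gene_id:
            continue
        if gene_to_genome is not None:
            ga = gene_to_genome.get(h.query_gene_id)
            gb = gene_to_genome.get(h.subject_gene_id)
            if ga is None or gb is None or ga == gb:
                continue
        if h.identity_pct <= spec.ortholog_identity_threshold_pct:
            continue
        if not spec.min_len_bp <= h.aligned_length_bp <= spec.max_len_bp:
            continue
        out.append(h)
    return out


def build_ortholog_sets(
    hits: Iterable[OrthologHit],
    gene_to_genome: Mapping[str, str],
) -> dict[tuple[str, str], OrthologSet]:
    """Group filtered hits into per-genome-pair ortholog sets.

    Each pair is keyed (genome_a, genome_b) with genome_a < genome_b
    lexicographically; hit direction is normalized accordingly.
    """
    sets: dict[tuple[str, str], OrthologSet] = {}
    for h in hits:
        ga = gene_to_genome[h.query_gene_id]
        gb = gene_to_genome[h.subject_gene_id]
        if ga == gb:
            continue
        if ga < gb:
            key, pair = (ga, gb), (h.query_gene_id, h.subject_gene_id)
        else:
            key, pair = (gb, ga), (h.subject_gene_id, h.query_gene_id)
        s = sets.setdefault(
            key,
            OrthologSet(key[0], key[1], pairs=[], identity_pct=[], aligned_length_bp=[]),
        )
        if pair in s.pairs:
            continue
        s.pairs.append(pair)
        s.identity_pct.append(h.identity_pct)
        s.aligned_length_bp.append(h.aligned_length_bp)
    return sets
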