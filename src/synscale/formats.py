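"""Readers and writers for all external representations.

GenBank flat files supply the gene order and 16S annotations; FASTA supplies
sequences for sketching; labeled matrices, ortholog hits, ortholog sets,
gene orders and taxonomy tables travel as plain TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DimensionError, FormatError, MissingDataError, SchemaError
from .types import GeneFeature, GeneOrder, LabeledMatrix, OrthologHit, OrthologSet

logger = logging.getLogger(__name__)

_16S_PRODUCT = "16s ribosomal rna"
_FEATURE_TYPES = ("CDS", "rRNA")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def _feature_gene_id(feat, record_id: str, index: int) -> str:
    q = feat.qualifiers
    for key in ("locus_tag", "gene", "protein_id"):
        if key in q and q[key]:
            return str(q[key][0])
    return f"{record_id}_f{index}"


def read_genbank_gene_order(
    path: str | Path,
    genome_id: str | None = None,
    require_16s: bool = False,
    sixteen_s_allowlist: Iterable[str] | None = None,
) -> tuple[GeneOrder, list[GeneFeature], list[GeneFeature]]:
    """Parse a GenBank flat file into a gene order plus feature lists.

    Returns ``(order, features, features_16s)``.  Genes are concatenated
    across records in file order (chromosome first, then plasmids), so ranks
    for later replicons follow those of earlier ones.  16S genes are rRNA
    features whose product contains "16S ribosomal RNA" (case-insensitive);
    alternatively an explicit ``sixteen_s_allowlist`` of gene_ids can be
    supplied (e.g. from an external rRNA-database confirmation).

    ``genome_id`` defaults to the first record's id.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises plain ValueError with context
        raise FormatError(f"{path}: unparsable GenBank file: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")

    gid = genome_id or records[0].id
    allow = set(sixteen_s_allowlist) if sixteen_s_allowlist is not None else None

    features: list[GeneFeature] = []
    sixteen_s: list[GeneFeature] = []
    ordered: list[str] = []
    total_len = 0
    fidx = 0
    for ridx, rec in enumerate(records):
        total_len += len(rec.seq)
        for feat in rec.features:
            if feat.type not in _FEATURE_TYPES:
                continue
            gene_id = _feature_gene_id(feat, rec.id, fidx)
            if gene_id in set(ordered):
                # locus tags repeat occasionally (e.g. join features); keep first
                continue
            product = str(feat.qualifiers.get("product", [""])[0])
            try:
                seq = str(feat.extract(rec.seq)) if len(rec.seq) else None
            except Exception:
                seq = None
            gf = GeneFeature(
                genome_id=gid,
                replicon_index=ridx,
                feature_index=fidx,
                gene_id=gene_id,
                gene_name=str(feat.qualifiers.get("gene", [""])[0]),
                product_description=product,
                start_bp=int(feat.location.start) + 1,
                end_bp=int(feat.location.end),
                strand="-" if feat.location.strand == -1 else "+",
                sequence=seq,
            )
            features.append(gf)
            ordered.append(gene_id)
            fidx += 1
            is_16s = (
                gene_id in allow
                if allow is not None
                else (feat.type == "rRNA" and _16S_PRODUCT in product.lower())
            )
            if is_16s:
                sixteen_s.append(gf)

    if not features:
        raise FormatError(f"{path}: empty genome (no CDS/rRNA features)")
    if require_16s and not sixteen_s:
        raise MissingDataError(f"{path}: no 16S ribosomal RNA feature found")

    order = GeneOrder(gid, tuple(ordered), genome_length_bp=max(total_len, 1))
    return order, features, sixteen_s


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file as an ordered mapping id -> uppercase sequence."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Labeled matrix TSV
# ---------------------------------------------------------------------------

def read_matrix_tsv(
    path: str | Path, kind: str, zero_is_missing: bool = False
) -> LabeledMatrix:
    """Read a labeled square matrix: first row and first column are labels.

    Asymmetric input is accepted (a warning is attached downstream where it
    matters); non-square bodies and non-numeric cells are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] != df.shape[1]:
        raise DimensionError(f"{path}: non-square matrix body {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError(f"{path}: row labels differ from column labels")
    values = np.empty(df.shape, dtype=float)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, column {j + 1}"
                ) from None
    m = LabeledMatrix(list(df.index.astype(str)), values, kind, zero_is_missing)
    if not m.is_symmetric(tol=1e-9):
        logger.warning("%s: matrix is asymmetric (accepted, flagged)", path)
    return m


def write_matrix_tsv(path: str | Path, m: LabeledMatrix) -> None:
    """Write in the canonical format: '.' decimal, 12 significant digits."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = (format(v, ".12g") for v in m.values[i])
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Ortholog hit tables (BLAST outfmt 6 column order)
# ---------------------------------------------------------------------------

def read_ortholog_hits(path: str | Path) -> list[OrthologHit]:
    """Parse a tab-separated hit table: query, subject, pident, length, ...

    Extra outfmt-6 columns are ignored; no filtering is applied here
    (identity/length filters live in :mod:`synscale.cohorts`).
    """
    path = Path(path)
    hits: list[OrthologHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SchemaError(
                    f"{path}:{lineno}: expected >= 4 columns "
                    "(query, subject, pident, length)"
                )
            try:
                pident = float(parts[2])
                length = int(float(parts[3]))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric pident/length "
                    f"({parts[2]!r}, {parts[3]!r})"
                ) from None
            hits.append(OrthologHit(parts[0], parts[1], pident, length))
    return hits


# ---------------------------------------------------------------------------
# Ortholog sets (genome_a, gene_a, genome_b, gene_b, identity, length)
# ---------------------------------------------------------------------------

_ORTHOSET_COLS = ["genome_a", "gene_a", "genome_b", "gene_b", "identity", "length"]


def write_ortholog_sets(path: str | Path, sets: Iterable[OrthologSet]) -> None:
    rows = []
    for s in sets:
        for i, (ga, gb) in enumerate(s.pairs):
            rows.append(
                {
                    "genome_a": s.genome_a,
                    "gene_a": ga,
                    "genome_b": s.genome_b,
                    "gene_b": gb,
                    "identity": "" if s.identity_pct is None else s.identity_pct[i],
                    "length": "" if s.aligned_length_bp is None else s.aligned_length_bp[i],
                }
            )
    pd.DataFrame(rows, columns=_ORTHOSET_COLS).to_csv(path, sep="\t", index=False)


def read_ortholog_sets(path: str | Path) -> list[OrthologSet]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in _ORTHOSET_COLS[:4] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    out: list[OrthologSet] = []
    for (ga, gb), grp in df.groupby(["genome_a", "genome_b"], sort=True):
        has_id = "identity" in grp and grp["identity"].notna().all()
        has_len = "length" in grp and grp["length"].notna().all()
        out.append(
            OrthologSet(
                genome_a=str(ga),
                genome_b=str(gb),
                pairs=list(zip(grp["gene_a"], grp["gene_b"])),
                identity_pct=list(map(float, grp["identity"])) if has_id else None,
                aligned_length_bp=list(map(int, grp["length"])) if has_len else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene orders as TSV (simulator output / pipeline input)
# ---------------------------------------------------------------------------

def write_gene_orders(path: str | Path, orders: Iterable[GeneOrder]) -> None:
    rows = []
    for o in orders:
        for rank, gid in enumerate(o.ordered_gene_ids, start=1):
            rows.append(
                {
                    "genome_id": o.genome_id,
                    "rank": rank,
                    "gene_id": gid,
                    "genome_length_bp": o.genome_length_bp,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_orders(path: str | Path) -> dict[str, GeneOrder]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "genome_id": str})
    for col in ("genome_id", "rank", "gene_id"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    out: dict[str, GeneOrder] = {}
    for gid, grp in df.groupby("genome_id", sort=False):
        grp = grp.sort_values("rank")
        length = int(grp["genome_length_bp"].iloc[0]) if "genome_length_bp" in grp else 1
        out[str(gid)] = GeneOrder(str(gid), tuple(grp["gene_id"]), length)
    return out


# ---------------------------------------------------------------------------
# Taxonomy tables
# ---------------------------------------------------------------------------

TAXONOMY_RANKS = ["phylum", "class", "order", "family", "genus"]


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Taxonomy table indexed by genome_id with rank columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns:
        raise SchemaError(f"{path}: missing column 'genome_id'")
    return df.set_index("genome_id")


def write_taxonomy(path: str | Path, table: pd.DataFrame) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False)
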