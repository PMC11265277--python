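import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from synscale.types import GeneOrder, LabeledMatrix, OrthologSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def random_distance_matrix(rng):
    """Symmetric random distance matrix factory with zero diagonal."""

    def make(n: int = 8, kind: str = "distance", zero_is_missing: bool = False):
        v = rng.uniform(0.05, 1.0, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        labels = [f"g{i:02d}" for i in range(n)]
        return LabeledMatrix(labels, v, kind, zero_is_missing)

    return make


def random_synteny_case(rng, max_genes: int = 6):
    """A random small genome pair with a one-to-one ortholog subset."""
    n_a = int(rng.integers(2, max_genes + 1))
    n_b = int(rng.integers(2, max_genes + 1))
    genes_a = [f"a{i}" for i in range(n_a)]
    genes_b = [f"b{i}" for i in range(n_b)]
    rng.shuffle(genes_a)
    rng.shuffle(genes_b)
    n_orth = int(rng.integers(2, min(n_a, n_b) + 1))
    pairs = list(zip(rng.permutation(genes_a)[:n_orth],
                     rng.permutation(genes_b)[:n_orth]))
    order_a = GeneOrder("A", tuple(genes_a), 1000)
    order_b = GeneOrder("B", tuple(genes_b), 1000)
    return order_a, order_b, OrthologSet("A", "B", [(str(a), str(b)) for a, b in pairs])


def genbank_text(records):
    """Render a minimal GenBank flat file.

    ``records`` is a list of (name, length, features) where each feature is
    (ftype, start, end, strand, qualifiers-dict).  Coordinates 1-based
    inclusive.
    """
    out = []
    for name, length, feats in records:
        # strict GenBank column layout: length right-justified ending col 40
        prefix = f"LOCUS       {name}"
        out.append(
            prefix
            + str(length).rjust(40 - len(prefix))
            + " bp    DNA     circular BCT 01-JAN-2024"
        )
        out.append("DEFINITION  synthetic test record.")
        out.append(f"ACCESSION   {name}")
        out.append(f"VERSION     {name}.1")
        out.append("KEYWORDS    .")
        out.append("SOURCE      synthetic construct")
        out.append("  ORGANISM  synthetic construct")
        out.append("            Bacteria.")
        out.append("FEATURES             Location/Qualifiers")
        out.append("     source          1.." + str(length))
        for ftype, start, end, strand, quals in feats:
            loc = f"{start}..{end}"
            if strand == "-":
                loc = f"complement({loc})"
            out.append(f"     {ftype:<16s}{loc}")
            for key, val in quals.items():
                out.append(f'                     /{key}="{val}"')
        out.append("ORIGIN")
        seq = ("acgt" * (length // 4 + 1))[:length]
        for i in range(0, length, 60):
            chunk = seq[i : i + 60]
            blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            out.append(f"{i + 1:>9} {blocks}")
        out.append("//")
    return "\n".join(out) + "\n"
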