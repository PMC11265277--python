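"""Distance/similarity conversions, covariance-based matrix augmentation,
and the Thr/Rem sparsity reductions.

The augmentation fuses a 16S distance matrix with synteny information:
``M = D16S @ cov(Dsyn)``, min-max normalized to [0, 1], symmetrized by
averaging with its transpose, diagonal forced to 0 (a genome is completely
similar to itself).  The product of two symmetric matrices is not symmetric
in general, so the symmetrization step is explicit; the largest
pre-symmetrization asymmetry is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, DomainError
from .types import LabeledMatrix, require_same_labels

logger = logging.getLogger(__name__)

_CONVERTIBLE = {"similarity": "distance", "distance": "similarity",
                "augmented": "similarity", "ani": "distance"}


@dataclass(frozen=True)
class AugmentationConfig:
    normalize: str = "minmax"
    force_symmetric: bool = True
    zero_diagonal: bool = True
    covariance_ddof: int = 1  # n-1 denominator

    def __post_init__(self) -> None:
        if self.normalize != "minmax":
            raise DomainError(f"unknown normalization {self.normalize!r}")


def to_distance(m: LabeledMatrix) -> LabeledMatrix:
    """Elementwise d = 1 - s.  Missing (zero) similarities map to distance 1
    by the same formula — the sparse convention is preserved verbatim."""
    if m.values.min() < -1e-12 or m.values.max() > 1 + 1e-12:
        raise DomainError("to_distance requires values in [0, 1]")
    return m.with_values(1.0 - m.values, kind="distance", zero_is_missing=False)


def to_similarity(m: LabeledMatrix) -> LabeledMatrix:
    """Inverse of :func:`to_distance`."""
    if m.values.min() < -1e-12 or m.values.max() > 1 + 1e-12:
        raise DomainError("to_similarity requires values in [0, 1]")
    return m.with_values(1.0 - m.values, kind="similarity", zero_is_missing=False)


def covariance_matrix(m: LabeledMatrix, ddof: int = 1) -> LabeledMatrix:
    """Covariance of the matrix's columns (columns as variables, rows as
    observations; denominator n - ddof)."""
    if m.n < 2:
        raise DimensionError("covariance requires n >= 2")
    cov = np.cov(m.values, rowvar=False, ddof=ddof)
    return LabeledMatrix(m.labels, np.atleast_2d(cov), kind="covariance")


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Map entries affinely onto [0, 1]; a constant matrix maps to zeros."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def augment(
    d16s: LabeledMatrix,
    dsyn: LabeledMatrix,
    cfg: AugmentationConfig = AugmentationConfig(),
) -> LabeledMatrix:
    """Covariance-scaled fusion of two distance matrices.

    Both inputs must already share labels and label order (reindex upstream
    otherwise).  Steps: matrix product with cov(dsyn); min-max normalization
    over all entries; optional symmetrization (M + M^T)/2; diagonal forced
    to 0.
    """
    require_same_labels(d16s, dsyn)
    cov = covariance_matrix(dsyn, ddof=cfg.covariance_ddof)
    prod = d16s.values @ cov.values
    norm = minmax_normalize(prod)
    if cfg.force_symmetric:
        asym = float(np.abs(norm - norm.T).max())
        if asym > 0:
            logger.info("augment: max pre-symmetrization asymmetry %.3e", asym)
        norm = (norm + norm.T) / 2.0
    if cfg.zero_diagonal:
        np.fill_diagonal(norm, 0.0)
    return LabeledMatrix(d16s.labels, norm, kind="augmented", zero_is_missing=True)


def reduce_thr(m: LabeledMatrix, threshold_pct: float = 82.0) -> LabeledMatrix:
    """Keep only entries strictly more similar than the threshold (the "Thr"
    reduction matching the ANI tools' reporting floor).

    Distance-scale matrices (kinds ``distance`` and ``augmented``) are
    thresholded on the similarity scale (1 - value) and returned on their own
    scale; removed entries become 0 with ``zero_is_missing=True``.
    """
    thr = threshold_pct / 100.0
    if m.kind in ("distance", "augmented"):
        sim = 1.0 - m.values
    elif m.kind in ("similarity", "ani"):
        sim = m.values if m.kind == "similarity" else m.values / (
            100.0 if m.values.max() > 1.0 else 1.0
        )
    else:
        raise DomainError(f"reduce_thr undefined for kind {m.kind!r}")
    keep = sim > thr
    out = np.where(keep, m.values, 0.0)
    return m.with_values(out, zero_is_missing=True)


def reduce_rem(m: LabeledMatrix, reference: LabeledMatrix) -> LabeledMatrix:
    """Keep only entries whose position is non-zero in the reference matrix
    (the "Rem" reduction masking to the ANI support)."""
    require_same_labels(m, reference)
    out = np.where(reference.values != 0.0, m.values, 0.0)
    return m.with_values(out, zero_is_missing=True)


def sparsity(m: LabeledMatrix) -> float:
    """Fraction of zero entries among all n^2 entries."""
    return float(np.count_nonzero(m.values == 0.0) / m.values.size)
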