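"""Median-of-ratios size-factor normalization and log2 transformation.

Raw read counts are not comparable across libraries because sequencing
depth varies.  The classical remedy for count data is a per-sample size
factor: the median, over genes, of the ratio between the sample's count
and a per-gene pseudo-reference (the geometric mean of that gene across
all samples).  Genes with a zero count in any sample are excluded from
the reference, the standard convention, because their geometric mean is
zero.  Factors are then rescaled so their geometric mean is one, which
makes downstream log2 values invariant to a global rescaling of depth.

Normalized values are ``log2(count / size_factor + pseudocount)`` with a
default pseudocount of 1, so a normalized count of ~4095 reads maps to
12 on the log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, SampleInfo

__all__ = ["NormalizedMatrix", "size_factors", "log2_normalize", "normalize"]


@dataclass
class NormalizedMatrix:
    """Log2-scale expression values plus the size factors that produced them."""

    gene_ids: list[str]
    values: np.ndarray  # (n_genes, n_samples), log2 scale
    size_factors: np.ndarray  # (n_samples,), geometric mean 1
    samples: list[SampleInfo]
    pseudocount: float = 1.0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def substrates(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.substrate not in out:
                out.append(s.substrate)
        return out

    def substrate_columns(self, substrate: str) -> np.ndarray:
        idx = [j for j, s in enumerate(self.samples) if s.substrate == substrate]
        if not idx:
            raise KeyError(f"unknown substrate {substrate!r}; have {self.substrates}")
        return np.asarray(idx, dtype=int)


def size_factors(em: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Raises if no gene has strictly positive counts in every sample — the
    reference would be empty and the factors undefined.
    """
    counts = em.counts.astype(float)
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "median-of-ratios size factors are undefined for this matrix"
        )
    ref = counts[positive]
    geomean = np.exp(np.mean(np.log(ref), axis=1))  # per-gene reference
    ratios = ref / geomean[:, None]
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return factors


def log2_normalize(
    em: ExpressionMatrix,
    factors: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """log2(count / size_factor + pseudocount), per gene and sample."""
    if factors is None:
        factors = size_factors(em)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (em.n_samples,):
        raise ValueError(
            f"expected {em.n_samples} size factors, got shape {factors.shape}"
        )
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    if pseudocount <= 0 and np.any(em.counts == 0):
        raise ValueError(
            "non-positive pseudocount with zero counts would produce "
            "non-finite log2 values"
        )
    values = np.log2(em.counts / factors[None, :] + pseudocount)
    return NormalizedMatrix(
        gene_ids=list(em.gene_ids),
        values=values,
        size_factors=factors,
        samples=list(em.samples),
        pseudocount=pseudocount,
    )


def normalize(em: ExpressionMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Convenience: size factors + log2 transform in one call."""
    return log2_normalize(em, size_factors(em), pseudocount=pseudocount)
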