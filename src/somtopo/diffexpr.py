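"""Simplified per-gene negative-binomial differential expression.

This is a deliberately small stand-in for a full count-GLM pipeline: an
externally produced DE table can always be supplied instead (see
:func:`somtopo.io.read_de_table`), and is preferred when available.

Model per gene: size-factor-scaled counts in each condition are treated
as draws from a negative binomial with mean μ and variance μ + φμ²; φ is
estimated by method of moments pooled across the two conditions and
truncated at zero.  The log2 fold change uses a +0.5 offset on both
means to keep zero-mean genes finite, and a two-sided Wald test on the
log2 difference uses the delta-method standard error derived from the NB
variance of the condition means.

Dispersion handling matters at typical replication (three per
condition).  A per-gene moment estimate is so noisy there that the Wald
statistic must be referred to a Student-t with n_s + n_ref − 2 degrees
of freedom to stay calibrated — and that heavy-tailed reference bounds
p-values away from zero, costing most of the power.  The table-level
entry point therefore defaults to a single dispersion pooled across the
whole gene set (the same information-sharing idea count-GLM tools use),
under which the variance is well determined and the normal reference is
both calibrated and powerful.  ``dispersion="per-gene"`` restores the
purely gene-wise fit with its t reference.  P-values are adjusted by
Benjamini–Hochberg (default) or Bonferroni.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DETable, ExpressionMatrix

__all__ = ["NBGeneFit", "fit_gene", "wald_test", "adjust_p",
           "pooled_dispersion", "de_table"]

_LFC_OFFSET = 0.5


@dataclass
class NBGeneFit:
    """Moment fit of one gene across two conditions (scaled counts).

    ``phi_shared`` records whether the dispersion was supplied from a
    pooled genome-wide estimate (normal Wald reference) or estimated
    from this gene's replicates alone (Student-t reference).
    """

    mu_s: float
    mu_ref: float
    phi: float  # dispersion, variance = mu + phi * mu^2
    n_s: int
    n_ref: int
    phi_shared: bool = False

    @property
    def log2fc(self) -> float:
        return float(
            np.log2((self.mu_s + _LFC_OFFSET) / (self.mu_ref + _LFC_OFFSET))
        )


def fit_gene(
    counts_s: np.ndarray,
    counts_ref: np.ndarray,
    size_factors_s: np.ndarray | None = None,
    size_factors_ref: np.ndarray | None = None,
    phi: float | None = None,
) -> NBGeneFit:
    """Method-of-moments NB fit for one gene, test vs reference condition.

    Requires at least two replicates per condition; with fewer there is
    no variance information and an externally computed DE table should
    be ingested instead.  An externally pooled dispersion may be passed
    as ``phi``; otherwise it is estimated from this gene's replicates.
    """
    counts_s = np.asarray(counts_s, dtype=float)
    counts_ref = np.asarray(counts_ref, dtype=float)
    if counts_s.size < 2 or counts_ref.size < 2:
        raise ValueError(
            "need >= 2 replicates per condition for the moment fit; "
            "supply an external DE table otherwise"
        )
    if size_factors_s is not None:
        counts_s = counts_s / np.asarray(size_factors_s, dtype=float)
    if size_factors_ref is not None:
        counts_ref = counts_ref / np.asarray(size_factors_ref, dtype=float)
    mu_s = float(counts_s.mean())
    mu_ref = float(counts_ref.mean())
    n_s, n_ref = counts_s.size, counts_ref.size
    if phi is not None:
        if phi < 0:
            raise ValueError("dispersion must be >= 0")
        return NBGeneFit(mu_s=mu_s, mu_ref=mu_ref, phi=float(phi),
                         n_s=n_s, n_ref=n_ref, phi_shared=True)
    # per-gene method of moments: (s^2 - mu) / mu^2, variance pooled
    # across the two conditions with (n-1) weights, at the pooled mean
    s2 = (
        (n_s - 1) * counts_s.var(ddof=1) + (n_ref - 1) * counts_ref.var(ddof=1)
    ) / (n_s + n_ref - 2)
    mu_bar = 0.5 * (mu_s + mu_ref)
    phi_hat = 0.0 if mu_bar == 0 else max(0.0, (s2 - mu_bar) / mu_bar**2)
    return NBGeneFit(mu_s=mu_s, mu_ref=mu_ref, phi=phi_hat,
                     n_s=n_s, n_ref=n_ref)


def wald_test(fit: NBGeneFit) -> float:
    """Two-sided p-value for log2FC ≠ 0 (delta-method Wald test).

    A pooled-dispersion fit is referred to the normal; a per-gene moment
    fit to a Student-t with n_s + n_ref − 2 df, which keeps the test
    calibrated when the variance itself is this noisy.
    """
    if fit.mu_s == 0 and fit.mu_ref == 0:
        return 1.0
    var_s = (fit.mu_s + fit.phi * fit.mu_s**2) / fit.n_s
    var_ref = (fit.mu_ref + fit.phi * fit.mu_ref**2) / fit.n_ref
    ln2sq = np.log(2.0) ** 2
    se2 = var_s / ((fit.mu_s + _LFC_OFFSET) ** 2 * ln2sq) + var_ref / (
        (fit.mu_ref + _LFC_OFFSET) ** 2 * ln2sq
    )
    if se2 == 0:
        return 1.0 if fit.log2fc == 0 else 0.0
    z = abs(fit.log2fc) / np.sqrt(se2)
    if fit.phi_shared:
        p = 2.0 * stats.norm.sf(z)
    else:
        p = 2.0 * stats.t.sf(z, df=fit.n_s + fit.n_ref - 2)
    return float(np.clip(p, np.nextafter(0, 1), 1.0))


def adjust_p(pvalues: np.ndarray, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: Benjamini–Hochberg step-up ('bh') or
    Bonferroni ('bonferroni')."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    method = method.lower()
    if method in ("bh", "fdr_bh", "fdr"):
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    if method == "bonferroni":
        return np.minimum(1.0, p * p.size)
    raise ValueError(f"unknown adjustment method {method!r}")


def pooled_dispersion(em: ExpressionMatrix, size_factors: np.ndarray) -> float:
    """Single genome-wide dispersion, pooled within-condition moments:
    φ̂ = max(0, Σ_g (s²_g − μ̄_g) / Σ_g μ̄_g²) over all conditions with
    replication."""
    sf = np.asarray(size_factors, dtype=float)
    scaled = em.counts / sf[None, :]
    num = 0.0
    den = 0.0
    for substrate in em.substrates:
        cols = em.substrate_columns(substrate)
        if cols.size < 2:
            continue
        mu = scaled[:, cols].mean(axis=1)
        s2 = scaled[:, cols].var(axis=1, ddof=1)
        keep = mu > 0
        num += float(np.sum(s2[keep] - mu[keep]))
        den += float(np.sum(mu[keep] ** 2))
    if den == 0:
        raise ValueError("no replicated condition with positive counts")
    return max(0.0, num / den)


def de_table(
    em: ExpressionMatrix,
    substrate: str,
    reference: str,
    size_factors: np.ndarray,
    padj_method: str = "bh",
    dispersion: str = "pooled",
) -> DETable:
    """DE statistics for every gene, ``substrate`` versus ``reference``.

    ``dispersion="pooled"`` (default) shares one moment dispersion across
    all genes and conditions and uses the normal Wald reference;
    ``"per-gene"`` uses gene-wise moment dispersions with the Student-t
    reference.  Vectorized across genes.
    """
    cols_s = em.substrate_columns(substrate)
    cols_ref = em.substrate_columns(reference)
    if cols_s.size < 2 or cols_ref.size < 2:
        raise ValueError(
            f"need >= 2 replicates for both {substrate!r} and {reference!r}"
        )
    if dispersion not in ("pooled", "per-gene"):
        raise ValueError("dispersion must be 'pooled' or 'per-gene'")
    sf = np.asarray(size_factors, dtype=float)
    ys = em.counts[:, cols_s] / sf[cols_s]
    yr = em.counts[:, cols_ref] / sf[cols_ref]
    n_s, n_ref = cols_s.size, cols_ref.size

    mu_s = ys.mean(axis=1)
    mu_ref = yr.mean(axis=1)
    if dispersion == "pooled":
        phi = np.full(em.n_genes, pooled_dispersion(em, sf))
    else:
        s2 = (
            (n_s - 1) * ys.var(axis=1, ddof=1)
            + (n_ref - 1) * yr.var(axis=1, ddof=1)
        ) / (n_s + n_ref - 2)
        mu_bar = 0.5 * (mu_s + mu_ref)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(
                mu_bar > 0, np.maximum(0.0, (s2 - mu_bar) / mu_bar**2), 0.0
            )
    lfc = np.log2((mu_s + _LFC_OFFSET) / (mu_ref + _LFC_OFFSET))
    ln2sq = np.log(2.0) ** 2
    se2 = (mu_s + phi * mu_s**2) / (n_s * (mu_s + _LFC_OFFSET) ** 2 * ln2sq) + (
        mu_ref + phi * mu_ref**2
    ) / (n_ref * (mu_ref + _LFC_OFFSET) ** 2 * ln2sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, np.abs(lfc) / np.sqrt(se2), 0.0)
    if dispersion == "pooled":
        pval = 2.0 * stats.norm.sf(z)
    else:
        pval = 2.0 * stats.t.sf(z, df=n_s + n_ref - 2)
    pval = np.where((mu_s == 0) & (mu_ref == 0), 1.0, pval)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    frame = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pval,
            "padj": adjust_p(pval, method=padj_method),
        },
        index=pd.Index(em.gene_ids, name="gene_id"),
    )
    return DETable(
        frame=frame,
        substrate=substrate,
        reference=reference,
        method=f"{padj_method}, {dispersion} dispersion",
    )
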