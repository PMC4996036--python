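"""Negative-binomial EM clustering baseline and the clustering-quality
score used to compare it against the SOM.

The baseline clusters genes on their *pattern* of condition effects
under a negative-binomial mixture, with each gene's overall abundance
profiled out — two genes with parallel fold-change profiles but very
different absolute expression belong to the same cluster.  This is the
defining behaviour of model-based count clustering tools, and exactly
the property the SOM comparison is designed to probe: a clustering that
discards absolute transcription level cannot line up with the secretome,
where detection frequency tracks absolute expression.

Model: counts y_gj ~ NB(mean s_j·exp(b_g + t_{k, c(j)}), dispersion φ)
with s_j the sample size factor, c(j) the sample's condition, t_k the
cluster's condition-effect vector (centered to mean zero) and φ shared
across genes.  Given t_k, the per-gene baseline b_g is profiled at its
Poisson maximum (fitted totals equal observed totals).  EM alternates
posterior responsibilities (E) with weighted fixed-point updates of the
effects, mixing weights and a method-of-moments dispersion update (M).
Each accepted iteration must not decrease the observed log-likelihood;
a proposal that would is rejected and the algorithm stops, so the
reported trace is monotone (generalized EM with an ascent check).

Clustering quality is scored as Spearman's rank correlation between the
clusters' global mean normalized transcription and their secreted
protein counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import ExpressionMatrix, SecretomeTable
from .normalization import NormalizedMatrix

__all__ = [
    "NBEMModel",
    "nbem_cluster",
    "cluster_secretion_correlation",
    "compare_methods",
]

_T_CLIP = 30.0  # effect bound on the natural-log scale


@dataclass
class NBEMModel:
    k: int
    cluster_profiles: np.ndarray  # (k, n_conditions), log scale, row-centered
    gene_baselines: np.ndarray  # (n_genes,), log scale, at the hard assignment
    dispersion: float
    responsibilities: np.ndarray  # (n_genes, k)
    hard_assignment: np.ndarray  # (n_genes,), 0-based cluster labels
    mixing: np.ndarray = field(default=None)
    loglik_trace: list[float] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan


def _log_nb(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Element-wise NB log-pmf with mean/dispersion parameterization;
    the φ → 0 limit is Poisson."""
    if phi < 1e-12:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = y * np.log(mu) - mu - gammaln(y + 1.0)
        return np.where(mu > 0, out, np.where(y == 0, 0.0, -np.inf))
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu))
        )
    return np.where(mu > 0, out, np.where(y == 0, 0.0, -np.inf))


class _NBEMState:
    """Precomputed data sufficient statistics for the EM updates."""

    def __init__(self, counts: np.ndarray, sf: np.ndarray, cond_idx: np.ndarray):
        self.y = counts.astype(float)  # (G, S)
        self.sf = sf  # (S,)
        self.cond_idx = cond_idx  # (S,) 0-based condition of each sample
        self.n_cond = int(cond_idx.max()) + 1
        self.ytot = self.y.sum(axis=1)  # (G,)
        G = self.y.shape[0]
        self.y_by_cond = np.zeros((G, self.n_cond))
        self.s_by_cond = np.zeros(self.n_cond)
        for c in range(self.n_cond):
            cols = np.flatnonzero(cond_idx == c)
            self.y_by_cond[:, c] = self.y[:, cols].sum(axis=1)
            self.s_by_cond[c] = sf[cols].sum()

    def mu(self, t: np.ndarray) -> np.ndarray:
        """Fitted means (G, k, S) with the baseline profiled out."""
        a = self.sf[None, :] * np.exp(t[:, self.cond_idx])  # (k, S)
        d = a.sum(axis=1)  # (k,)
        return self.ytot[:, None, None] * (a / d[:, None])[None, :, :]

    def loglik_matrix(self, t: np.ndarray, phi: float) -> np.ndarray:
        """(G, k) per-gene per-cluster log-likelihoods."""
        mu = self.mu(t)
        return _log_nb(self.y[:, None, :], mu, phi).sum(axis=2)


def _observed_loglik(L: np.ndarray, log_pi: np.ndarray) -> float:
    return float(logsumexp(L + log_pi[None, :], axis=1).sum())


def _moment_dispersion(y: np.ndarray, sf: np.ndarray, cond_idx: np.ndarray) -> float:
    """Pooled within-condition method-of-moments dispersion estimate."""
    num = 0.0
    den = 0.0
    scaled = y / sf[None, :]
    for c in np.unique(cond_idx):
        cols = np.flatnonzero(cond_idx == c)
        if cols.size < 2:
            continue
        mu = scaled[:, cols].mean(axis=1)
        s2 = scaled[:, cols].var(axis=1, ddof=1)
        keep = mu > 0
        num += float(np.sum(s2[keep] - mu[keep]))
        den += float(np.sum(mu[keep] ** 2))
    return max(0.0, num / den) if den > 0 else 0.0


def nbem_cluster(
    em: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    size_factors: np.ndarray | None = None,
) -> NBEMModel:
    """Fit the NB mixture of condition-effect patterns by EM.

    Initial cluster profiles come from k distinct genes drawn with the
    seeded generator; the shared dispersion starts at its pooled
    within-condition moment estimate.  Stops when the log-likelihood
    improves by less than ``tol`` or after ``max_iter`` iterations.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > em.n_genes:
        raise ValueError(f"k={k} exceeds the number of genes ({em.n_genes})")
    if size_factors is None:
        from .normalization import size_factors as _sf

        size_factors = _sf(em)
    sf = np.asarray(size_factors, dtype=float)
    conditions = em.substrates
    cond_of = {c: i for i, c in enumerate(conditions)}
    cond_idx = np.array([cond_of[s.substrate] for s in em.samples])
    state = _NBEMState(em.counts, sf, cond_idx)
    G = em.n_genes

    rng = np.random.default_rng(seed)
    seeds = rng.choice(G, size=k, replace=False)
    t = np.log((state.y_by_cond[seeds] + 0.5) / state.s_by_cond[None, :])
    t = np.clip(t - t.mean(axis=1, keepdims=True), -_T_CLIP, _T_CLIP)
    phi = _moment_dispersion(state.y, sf, cond_idx)
    log_pi = np.full(k, -np.log(k))

    if k == G:
        warnings.warn(
            "k equals the number of genes; each gene is its own cluster"
        )
        t = np.log((state.y_by_cond + 0.5) / state.s_by_cond[None, :])
        t = np.clip(t - t.mean(axis=1, keepdims=True), -_T_CLIP, _T_CLIP)
        resp = np.eye(G)
        L = state.loglik_matrix(t, phi)
        ll = _observed_loglik(L, np.full(G, -np.log(G)))
        return _finalize(state, t, phi, resp, [ll], conditions, em.gene_ids,
                         np.full(G, -np.log(G)))

    L = state.loglik_matrix(t, phi)
    ll = _observed_loglik(L, log_pi)
    trace = [ll]
    for _ in range(max_iter):
        # E-step
        logr = L + log_pi[None, :]
        logr -= logsumexp(logr, axis=1, keepdims=True)
        resp = np.exp(logr)

        # M-step proposals
        new_log_pi = np.log(resp.mean(axis=0) + 1e-300)
        new_t = t
        for _inner in range(2):
            a = state.sf[None, :] * np.exp(new_t[:, state.cond_idx])  # (k, S)
            d = a.sum(axis=1)
            eb = state.ytot[:, None] / d[None, :]  # (G, k) profiled baselines
            num = resp.T @ state.y_by_cond  # (k, C)
            den = (resp * eb).sum(axis=0)[:, None] * state.s_by_cond[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                cand = np.log(num) - np.log(den)
            cand = np.where(np.isfinite(cand), cand, -_T_CLIP)
            new_t = np.clip(cand - cand.mean(axis=1, keepdims=True),
                            -_T_CLIP, _T_CLIP)
        mu = state.mu(new_t)
        w = resp[:, :, None]
        num_phi = float(np.sum(w * ((state.y[:, None, :] - mu) ** 2 - mu)))
        den_phi = float(np.sum(w * mu**2))
        new_phi = max(0.0, num_phi / den_phi) if den_phi > 0 else phi

        new_L = state.loglik_matrix(new_t, new_phi)
        new_ll = _observed_loglik(new_L, new_log_pi)
        if new_ll < ll - 1e-10:
            # ascent check failed: keep current parameters and stop
            break
        improved = new_ll - ll
        t, phi, log_pi, L, ll = new_t, new_phi, new_log_pi, new_L, new_ll
        trace.append(ll)
        if improved < tol:
            break

    logr = L + log_pi[None, :]
    logr -= logsumexp(logr, axis=1, keepdims=True)
    resp = np.exp(logr)
    return _finalize(state, t, phi, resp, trace, conditions, em.gene_ids, log_pi)


def _finalize(state, t, phi, resp, trace, conditions, gene_ids, log_pi) -> NBEMModel:
    hard = np.argmax(resp, axis=1)
    a = state.sf[None, :] * np.exp(t[:, state.cond_idx])
    d = a.sum(axis=1)
    with np.errstate(divide="ignore"):
        baselines = np.log(state.ytot) - np.log(d[hard])
    return NBEMModel(
        k=t.shape[0],
        cluster_profiles=t,
        gene_baselines=baselines,
        dispersion=phi,
        responsibilities=resp,
        hard_assignment=hard,
        mixing=np.exp(log_pi),
        loglik_trace=trace,
        conditions=list(conditions),
        gene_ids=list(gene_ids),
    )


# ---------------------------------------------------------------------------
# clustering-quality score


def _cluster_vectors(
    labels: np.ndarray,
    nm: NormalizedMatrix,
    st: SecretomeTable,
    mode: str = "distinct",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    gene_to_cluster = dict(zip(nm.gene_ids, labels))
    means = np.array(
        [nm.values[labels == c].mean() for c in uniq]
    )
    counts = np.zeros(uniq.size)
    pos = {c: i for i, c in enumerate(uniq)}
    seen: set[str] = set()
    for rec in st.detected_records():
        c = gene_to_cluster.get(rec.gene_id)
        if c is None:
            continue
        if mode == "distinct":
            if rec.protein_id in seen:
                continue
            seen.add(rec.protein_id)
        counts[pos[c]] += 1
    return uniq, means, counts


def cluster_secretion_correlation(
    clustering,
    nm: NormalizedMatrix,
    st: SecretomeTable,
    mode: str = "distinct",
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman correlation between cluster-level mean transcription and
    secreted-protein counts.

    ``clustering`` is an array of labels aligned with ``nm.gene_ids`` or
    a mapping gene_id → label.  Ties are handled by average ranks; the
    two-sided p-value uses the large-sample t approximation, or the
    exact permutation distribution when ``exact`` is set (allowed for up
    to 10 clusters).  A constant vector leaves ρ undefined (NaN).
    """
    if isinstance(clustering, dict):
        labels = np.array([clustering[g] for g in nm.gene_ids])
    else:
        labels = np.asarray(clustering)
        if labels.shape != (nm.n_genes,):
            raise ValueError("clustering labels must align with nm.gene_ids")
    uniq, means, counts = _cluster_vectors(labels, nm, st, mode=mode)
    if uniq.size < 3:
        raise ValueError("need at least 3 clusters for a rank correlation")
    if np.all(means == means[0]) or np.all(counts == counts[0]):
        warnings.warn("constant cluster vector; Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(means, counts)
    if exact:
        if uniq.size > 10:
            raise ValueError("exact permutation p only supported for <= 10 clusters")
        p = _exact_spearman_p(means, counts)
    return float(rho), float(p)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(len(ry))):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def compare_methods(
    som_model,
    nbem_model: NBEMModel,
    nm: NormalizedMatrix,
    st: SecretomeTable,
    mode: str = "distinct",
) -> pd.DataFrame:
    """Side-by-side clustering-quality report for the SOM and the NB-EM
    baseline: cluster count, genes-per-cluster resolution, Spearman ρ, p."""
    if set(som_model.gene_ids) != set(nbem_model.gene_ids):
        raise ValueError("SOM and NB-EM models cover different gene sets")
    som_labels = np.array(
        [dict(zip(som_model.gene_ids, som_model.assignment))[g] for g in nm.gene_ids]
    )
    nbem_labels = np.array(
        [dict(zip(nbem_model.gene_ids, nbem_model.hard_assignment))[g]
         for g in nm.gene_ids]
    )
    rows = []
    for method, labels, k in (
        ("SOM", som_labels, som_model.map_units),
        ("NBEM", nbem_labels, nbem_model.k),
    ):
        rho, p = cluster_secretion_correlation(labels, nm, st, mode=mode)
        rows.append(
            {
                "method": method,
                "k": k,
                "genes_per_cluster": nm.n_genes / k,
                "spearman_rho": rho,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
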