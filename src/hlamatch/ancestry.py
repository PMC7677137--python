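"""Supervised ancestry-proportion estimation and ancestry-group assignment.

Estimates each individual's ancestry proportions q over K=3 fixed parental
populations (African, European, Native American) from biallelic SNP
dosages, by maximizing the binomial likelihood

    L(q) = prod_j Binom(g_j | 2, sum_k q_k f_kj)

over the simplex via EM, with the parental allele frequencies f treated as
known (the supervised special case of maximum-likelihood admixture
estimation).  Also provides the downstream group assignments used in the
match analysis: rank-based quartiles of African ancestry and the MHC
African-dosage classes 0/1/2 obtained by rounding each chromosome's
African fraction to the nearest integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AncestryEstimate",
    "QuartileAssignment",
    "estimate_ancestry",
    "estimate_ancestry_batch",
    "assign_quartiles",
    "mhc_dosage",
    "variance_explained",
]

_FREQ_CLAMP = 1e-6
_EM_TOL = 1e-7
_EM_MAX_ITER = 1000


@dataclass
class AncestryEstimate:
    """Result of one supervised ancestry fit."""

    q_hat: np.ndarray  # (K,) simplex point
    loglik: float
    iterations: int
    converged: bool
    loglik_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = float(np.sum(self.q_hat))
        if not math.isclose(s, 1.0, abs_tol=1e-8):
            raise ValueError(f"q_hat must sum to 1, got {s}")


def _prepare(dosages, freqs):
    g = np.asarray(dosages, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 2:
        raise ValueError("parental frequencies must be a (n_snps, K) matrix")
    if g.shape[-1] != f.shape[0]:
        raise ValueError("dosage vector and frequency matrix disagree on SNP count")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite parental frequencies")
    mask = np.isfinite(g)
    if np.any((g[mask] < 0) | (g[mask] > 2)):
        raise ValueError("dosages must lie in {0,1,2} (or be missing)")
    f = np.clip(f, _FREQ_CLAMP, 1.0 - _FREQ_CLAMP)
    return g, f, mask


def estimate_ancestry(
    dosages: np.ndarray,
    parental_freqs: np.ndarray,
    tol: float = _EM_TOL,
    max_iter: int = _EM_MAX_ITER,
    return_trace: bool = False,
) -> AncestryEstimate:
    """Estimate one individual's ancestry proportions by EM.

    Missing dosages (NaN) are skipped.  Convergence is declared when the
    log-likelihood gain drops below ``tol``.  If the parental populations
    are indistinguishable at every SNP the likelihood is flat; the uniform
    vector is returned with ``converged=False``.
    """
    g, f, mask = _prepare(dosages, parental_freqs)
    if g.ndim != 1:
        raise ValueError("estimate_ancestry takes a single dosage vector")
    if not mask.any():
        raise ValueError("all SNPs missing: ancestry is not estimable")
    g = g[mask]
    f = f[mask]
    k = f.shape[1]
    q = np.full(k, 1.0 / k)
    if float(np.max(f.max(axis=1) - f.min(axis=1))) < 1e-9:
        p = f @ q
        ll = float(np.sum(g * np.log(p) + (2 - g) * np.log1p(-p)))
        return AncestryEstimate(q_hat=q, loglik=ll, iterations=0, converged=False,
                                loglik_trace=np.array([ll]) if return_trace else None)
    n2 = 2.0 * len(g)
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = f @ q
        ll = float(np.sum(g * np.log(p) + (2 - g) * np.log1p(-p)))
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll
        # E-step responsibilities folded into the closed-form M-step
        q = q * ((g / p) @ f + ((2 - g) / (1 - p)) @ (1 - f)) / n2
        q = q / q.sum()
    p = f @ q
    ll = float(np.sum(g * np.log(p) + (2 - g) * np.log1p(-p)))
    return AncestryEstimate(
        q_hat=q, loglik=ll, iterations=it, converged=converged,
        loglik_trace=np.array(trace) if return_trace else None,
    )


def estimate_ancestry_batch(
    dosages: np.ndarray,
    parental_freqs: np.ndarray,
    tol: float = _EM_TOL,
    max_iter: int = _EM_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized EM over a whole cohort.

    Returns ``(Q, loglik, iterations, converged)`` with ``Q`` of shape
    (n, K).  Missing dosages (NaN) are masked out per individual.
    """
    g = np.asarray(dosages, dtype=float)
    if g.ndim != 2:
        raise ValueError("batch estimation takes an (n, n_snps) dosage matrix")
    _, f, mask = _prepare(g, parental_freqs)
    if not mask.all(axis=1).all() and np.any(~mask.any(axis=1)):
        raise ValueError("some individuals have all SNPs missing")
    w = mask.astype(float)
    g = np.where(mask, g, 0.0)
    n, _ = g.shape
    k = f.shape[1]
    denom = 2.0 * w.sum(axis=1)
    q = np.full((n, k), 1.0 / k)
    prev = np.full(n, -np.inf)
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    ll = prev.copy()
    one_m_f = 1.0 - f
    for it in range(1, max_iter + 1):
        active = ~converged
        if not active.any():
            break
        qa = q[active]
        p = qa @ f.T
        ga = g[active]
        wa = w[active]
        lla = np.sum(wa * (ga * np.log(p) + (2 - ga) * np.log1p(-p)), axis=1)
        ll[active] = lla
        gain = lla - prev[active]
        newly = (gain < tol) & (iters[active] > 0)
        prev[active] = lla
        iters[active] += 1
        qa = qa * ((wa * ga / p) @ f + (wa * (2 - ga) / (1 - p)) @ one_m_f)
        qa = qa / denom[active, None]
        qa = qa / qa.sum(axis=1, keepdims=True)
        idx = np.flatnonzero(active)
        q[idx[~newly]] = qa[~newly]
        converged[idx[newly]] = True
    flat = (f.max(axis=1) - f.min(axis=1)).max() < 1e-9
    if flat:
        converged[:] = False
    return q, ll, iters, converged


@dataclass
class QuartileAssignment:
    """Rank-based quartiles of African ancestry (Q1 = least African)."""

    labels: np.ndarray  # "Q1".."Q4" per individual, input order
    boundaries: tuple[float, float, float, float]  # upper bound per quartile
    degenerate: bool  # boundaries not strictly increasing (heavy ties)


def assign_quartiles(q_afr_values: np.ndarray) -> QuartileAssignment:
    """Partition a sample into quartiles of increasing African ancestry.

    Rank-based with ties broken by stable input order, so the partition is
    invariant under monotone transformations of the values.  Degenerate
    boundaries (ties spanning quartile cuts) are flagged, not raised.
    """
    values = np.asarray(q_afr_values, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("quartile assignment needs at least 4 values")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = []
    for qi, chunk in enumerate(np.array_split(np.arange(n), 4)):
        idx = order[chunk]
        labels[idx] = f"Q{qi + 1}"
        bounds.append(float(values[idx].max()))
    degenerate = any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:]))
    return QuartileAssignment(
        labels=labels.astype(str), boundaries=tuple(bounds), degenerate=degenerate
    )


def mhc_dosage(mhc_afr: tuple[float, float]) -> int:
    """Number of chromosomes with an African MHC segment (0, 1 or 2).

    Each haplotype's African fraction is rounded to the nearest integer
    (0.5 rounds up, toward African) and the two are summed; intermediate
    fractions arise from chromosomes with mixed ancestry within the
    segment.
    """
    total = 0
    for a in mhc_afr:
        a = float(a)
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"MHC African fraction {a} outside [0,1]")
        total += int(math.floor(a + 0.5))
    return total


def variance_explained(labels: np.ndarray, values: np.ndarray) -> float:
    """Fraction of variance in ``values`` explained by the grouping.

    R² = 1 - SS_within / SS_total, identical to the R² of an OLS
    regression of the values on group indicators.
    """
    labels = np.asarray(labels)
    values = np.asarray(values, dtype=float)
    if labels.shape != values.shape:
        raise ValueError("labels and values must have equal length")
    cats = np.unique(labels)
    if len(cats) < 2:
        raise ValueError("variance explained needs at least 2 categories")
    sst = float(np.sum((values - values.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("values have zero total variance")
    ssw = 0.0
    for c in cats:
        v = values[labels == c]
        ssw += float(np.sum((v - v.mean()) ** 2))
    return 1.0 - ssw / sst
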