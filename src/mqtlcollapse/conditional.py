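"""Conditional analysis: D' linkage disequilibrium, pruning, index-SNP conditioning.

Regions that sit near a known single-variant mQTL are not scanned for novel
signal; instead the collapsed rare-variant set is re-tested with the index
SNP in the covariates, after removing region variants in high LD with it
(D' >= 0.8).  D' is used rather than r^2 because the attainable range of
r^2 depends on the allele-frequency difference between a common index SNP
and rare variants, whereas D' is normalized to [0, 1].

D' between unphased genotypes is estimated by the two-locus EM algorithm on
hard calls (resolving double heterozygotes); fractional dosages fall back to
a composite (covariance-based) estimator, with the method recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skat import KernelTestResult, WeightSpec, skat_test

__all__ = [
    "LDStats",
    "estimate_dprime",
    "prune_by_dprime",
    "conditional_skat",
    "probe_overlap_conditioning",
]

EM_MAX_ITER = 50
EM_TOL = 1e-8
HARD_CALL_TOL = 1e-6


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    r2: float
    method: str  # "em_haplotype" | "composite"


def _em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """EM haplotype frequencies (pAB, pAb, paB, pab) from hard-call genotypes.

    A/a are minor/major alleles at locus 1, B/b at locus 2; ``g`` counts
    minor alleles.  Only the 1/1 double-heterozygote cell is ambiguous.
    """
    n = g1.shape[0]
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.sum((g1 == a) & (g2 == b))
    n_dh = counts[1, 1]
    # haplotype counts from the unambiguous genotype cells; only the 1/1
    # double heterozygote leaves phase unresolved
    base = np.zeros(4)  # AB, Ab, aB, ab
    contrib = {
        (0, 0): (0, 0, 0, 2),
        (0, 1): (0, 0, 1, 1),
        (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1),
        (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0),
        (2, 1): (1, 1, 0, 0),
        (2, 2): (2, 0, 0, 0),
    }
    for (a, b), (hAB, hAb, haB, hab) in contrib.items():
        c = counts[a, b]
        base += c * np.array([hAB, hAb, haB, hab], dtype=float)
    freqs = np.full(4, 0.25)
    total = 2.0 * n
    for _ in range(EM_MAX_ITER):
        denom = freqs[0] * freqs[3] + freqs[1] * freqs[2]
        frac_cis = 0.5 if denom <= 0 else freqs[0] * freqs[3] / denom
        new = base + n_dh * np.array(
            [frac_cis, 1 - frac_cis, 1 - frac_cis, frac_cis]
        )
        new /= total
        if np.max(np.abs(new - freqs)) < EM_TOL:
            freqs = new
            break
        freqs = new
    return freqs


def estimate_dprime(g1: np.ndarray, g2: np.ndarray) -> LDStats:
    """Pairwise LD between two dosage vectors.

    Hard calls go through the two-locus EM; fractional dosages use the
    composite covariance estimator D = cov(g1, g2) / 2.  D' = |D| / Dmax
    with the usual frequency-dependent bound; r2 = D^2 / (pA qA pB qB).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.var() <= 0 or g2.var() <= 0:
        raise ValueError("monomorphic variant: LD undefined")
    hard = np.allclose(g1, np.rint(g1), atol=HARD_CALL_TOL) and np.allclose(
        g2, np.rint(g2), atol=HARD_CALL_TOL
    )
    if hard:
        h1 = np.rint(g1).astype(int)
        h2 = np.rint(g2).astype(int)
        freqs = _em_haplotype_freqs(h1, h2)
        pA = freqs[0] + freqs[1]
        pB = freqs[0] + freqs[2]
        D = freqs[0] - pA * pB
        method = "em_haplotype"
    else:
        pA = g1.mean() / 2.0
        pB = g2.mean() / 2.0
        D = float(np.cov(g1, g2)[0, 1]) / 2.0
        method = "composite"
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = 0.0 if dmax <= 0 else min(abs(D) / dmax, 1.0)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = 0.0 if denom <= 0 else min(D * D / denom, 1.0)
    return LDStats(D=float(D), D_prime=float(d_prime), r2=float(r2), method=method)


def prune_by_dprime(
    G: np.ndarray,
    variant_ids: list[str],
    index_dosages: np.ndarray,
    threshold: float = 0.8,
) -> list[str]:
    """Drop region variants with D' >= threshold against any index SNP.

    ``index_dosages`` may be one vector or a samples x k matrix of several
    index SNPs; pruning then uses the max D' over indices.  Returns retained
    variant ids (the region stays eligible iff >= 2 remain).
    """
    G = np.asarray(G, dtype=float)
    idx = np.asarray(index_dosages, dtype=float)
    if idx.ndim == 1:
        idx = idx[:, None]
    retained = []
    for j, vid in enumerate(variant_ids):
        dmax = max(
            estimate_dprime(G[:, j], idx[:, k]).D_prime for k in range(idx.shape[1])
        )
        if dmax < threshold:
            retained.append(vid)
    return retained


def _stack_covariates(
    covariates: np.ndarray | None, index_dosages: np.ndarray
) -> np.ndarray:
    idx = np.asarray(index_dosages, dtype=float)
    if idx.ndim == 1:
        idx = idx[:, None]
    if covariates is None:
        return idx
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([X, idx])


def conditional_skat(
    y: np.ndarray,
    covariates: np.ndarray | None,
    index_dosages: np.ndarray,
    G_pruned: np.ndarray,
    weight_spec: WeightSpec | None = None,
    mafs: np.ndarray | None = None,
) -> KernelTestResult:
    """Kernel test of the pruned region with the index SNP(s) as covariates.

    A second pass for significant hits can pass the full matrix of index
    SNPs at the locus through ``index_dosages``.
    """
    X = _stack_covariates(covariates, index_dosages)
    return skat_test(y, X, G_pruned, weight_spec, mafs=mafs)


def probe_overlap_conditioning(
    y: np.ndarray,
    covariates: np.ndarray | None,
    overlap_dosage: np.ndarray,
    G: np.ndarray,
    weight_spec: WeightSpec | None = None,
    mafs: np.ndarray | None = None,
) -> dict:
    """Re-test a region with a probe-overlapping variant as a covariate.

    Returns both p-values and the attenuation on the log10 scale
    (log10 p_cond - log10 p_uncond; positive means the signal weakened).
    """
    overlap = np.asarray(overlap_dosage, dtype=float)
    if overlap.var() <= 0:
        raise ValueError("overlapping variant is monomorphic in the analyzed subset")
    uncond = skat_test(y, covariates, G, weight_spec, mafs=mafs)
    cond = conditional_skat(y, covariates, overlap, G, weight_spec, mafs=mafs)
    return {
        "p_unconditional": uncond.p_value,
        "p_conditional": cond.p_value,
        "log10_attenuation": float(
            np.log10(cond.p_value) - np.log10(uncond.p_value)
        ),
        "result_unconditional": uncond,
        "result_conditional": cond,
    }
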