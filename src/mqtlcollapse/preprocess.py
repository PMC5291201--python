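"""Variant QC, methylation rank-normalization and covariate residualization.

Variant filters follow the conventions of imputed-array mQTL studies: keep a
variant iff its Hardy-Weinberg exact p exceeds a floor, its folded MAF is at
or below the low-frequency cutoff, and its imputation info score exceeds a
quality floor.  Methylation values are mapped per probe to normal quantiles
of their ranks (rankit offset, c = 0.5) and then residualized on the full
covariate table by OLS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_variants",
    "rank_inverse_normal",
    "residualize",
    "impute_missing_dosages",
    "hwe_exact_pvalue",
    "folded_maf",
    "align_samples",
]

logger = logging.getLogger(__name__)


def folded_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from dosages in [0, 2], folded to (0, 0.5]."""
    freq = float(np.nanmean(dosages)) / 2.0
    return min(freq, 1.0 - freq)


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test (mid-less, standard exact formulation).

    Sums the probabilities of all heterozygote counts no more likely than the
    observed one, conditional on the allele counts.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # fold so "rare" is the minor allele
        n_rare = 2 * n - n_rare
        n_hom_minor = n_hom_major
    # probabilities over all feasible het counts with the same parity
    het_min = n_rare % 2
    hets = np.arange(het_min, n_rare + 1, 2)
    logp = np.zeros_like(hets, dtype=float)
    from scipy.special import gammaln

    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_r + 1)
        - gammaln(hom_c + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise ValueError("observed het count inconsistent with allele count parity")
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return min(p, 1.0)


def filter_variants(
    variants: pd.DataFrame,
    hwe_min: float = 5e-7,
    maf_max: float = 0.05,
    info_min: float = 0.8,
) -> pd.DataFrame:
    """QC filter: HWE p > hwe_min, MAF <= maf_max, info score > info_min.

    Missing info scores (hard-called data) are treated as passing, with a log
    note.  Threshold directions match the stated rules exactly, so boundary
    values behave as quoted (MAF at the cutoff is kept, info at the floor is
    dropped).
    """
    if not (0 < maf_max <= 0.5):
        raise ValueError("maf_max must lie in (0, 0.5]")
    if len(variants) == 0:
        return variants.copy()
    info = variants["info_score"] if "info_score" in variants else pd.Series(
        np.nan, index=variants.index
    )
    missing_info = info.isna()
    if missing_info.any():
        logger.info(
            "%d variants without info score treated as passing (hard calls)",
            int(missing_info.sum()),
        )
    keep = (
        (variants["hwe_p"] > hwe_min)
        & (variants["maf"] <= maf_max)
        & (missing_info | (info > info_min))
    )
    return variants.loc[keep].copy()


def rank_inverse_normal(values: np.ndarray, c: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform with rankit offset.

    Maps value with rank k (average ranks for ties) to
    ``Phi^{-1}((k - c) / (n - 2c + 1))``.  Missing values are passed through
    as NaN and excluded from the ranking.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    x = values[mask]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing values to rank-normalize")
    if np.all(x == x[0]):
        raise ValueError("all values identical: rank transform undefined")
    ranks = stats.rankdata(x, method="average")
    out[mask] = stats.norm.ppf((ranks - c) / (x.size - 2 * c + 1))
    return out


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on [1, covariates]; orthogonal to every column."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        X = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = np.where(diag < 1e-10 * max(diag.max(), 1.0))[0]
    if bad.size:
        raise ValueError(f"rank-deficient covariate design; collinear columns {bad.tolist()}")
    return y - q @ (q.T @ y)


def impute_missing_dosages(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries per variant column.

    ``dosages`` is samples x variants; a fully missing variant is an error.
    """
    d = np.array(dosages, dtype=float, copy=True)
    if d.ndim == 1:
        d = d[:, None]
        squeeze = True
    else:
        squeeze = False
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = ~np.isfinite(col)
        if miss.all():
            raise ValueError(f"variant column {j} is fully missing")
        if miss.any():
            col[miss] = col[~miss].mean()
    return d[:, 0] if squeeze else d


def align_samples(*frames: pd.Index) -> pd.Index:
    """Intersection of sample id sets, kept in the order of the first index."""
    if not frames:
        raise ValueError("no sample indexes given")
    common = set(frames[0])
    for idx in frames[1:]:
        common &= set(idx)
    if not common:
        raise ValueError("no samples shared across inputs")
    return pd.Index([s for s in frames[0] if s in common])
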