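"""Robustness diagnostics: LD pruning, leave-one-out stability, outlier summaries.

A region-level hit is only convincing if it is a combined effect: removing
any single variant should leave the signal largely intact.  Variants are
first pruned pairwise (greedy, r^2 >= threshold in position order) so that a
variant and its near-duplicate cannot cover for each other, then the kernel
test is re-run leaving each retained variant out in turn.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .skat import WeightSpec, skat_test

__all__ = ["ld_prune", "leave_one_out", "carrier_summary"]

REPORT_THRESHOLD = 1e-14
CARRIER_MIN_DOSAGE = 0.5


def ld_prune(G: np.ndarray, r2_threshold: float = 0.8) -> list[int]:
    """Greedy pairwise pruning in position (column) order.

    Walks columns left to right and keeps a column only if its squared
    correlation with every previously kept column is below the threshold, so
    of any correlated pair the later variant is dropped.  Deterministic and
    idempotent.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if G.shape[1] == 0:
        raise ValueError("need at least one variant")
    kept: list[int] = []
    for j in range(G.shape[1]):
        if G[:, j].var() <= 0:
            continue
        ok = True
        for k in kept:
            r = np.corrcoef(G[:, j], G[:, k])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def leave_one_out(
    y: np.ndarray,
    covariates: np.ndarray | None,
    G_pruned: np.ndarray,
    weight_spec: WeightSpec | None = None,
    variant_ids: list[str] | None = None,
    mafs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Kernel test with each variant removed in turn, plus the all-in reference.

    Returns one row per removed variant and one reference row
    (removed = "none"); a plot of -log10 p against the removed variant, with
    the reference p and the study-wide threshold (1e-14) as guide lines, is
    the intended display.
    """
    G_pruned = np.asarray(G_pruned, dtype=float)
    p = G_pruned.shape[1]
    if p < 3:
        raise ValueError(
            "leave-one-out needs >= 3 pruned variants so every removal leaves >= 2"
        )
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(p)]
    mafs = np.asarray(mafs, dtype=float) if mafs is not None else None
    ref = skat_test(y, covariates, G_pruned, weight_spec, mafs=mafs)
    rows = [
        {
            "removed": "none",
            "p_value": ref.p_value,
            "n_variants_tested": p,
            "reference_p": ref.p_value,
            "threshold": REPORT_THRESHOLD,
        }
    ]
    for j in range(p):
        keep = [k for k in range(p) if k != j]
        sub_mafs = mafs[keep] if mafs is not None else None
        res = skat_test(y, covariates, G_pruned[:, keep], weight_spec, mafs=sub_mafs)
        rows.append(
            {
                "removed": variant_ids[j],
                "p_value": res.p_value,
                "n_variants_tested": p - 1,
                "reference_p": ref.p_value,
                "threshold": REPORT_THRESHOLD,
            }
        )
    return pd.DataFrame(rows)


def carrier_summary(y: np.ndarray, G: np.ndarray, variant_ids: list[str] | None = None) -> pd.DataFrame:
    """Box-plot data: five-number summaries of y for carriers vs non-carriers.

    A sample is a carrier of a variant if its dosage is >= 0.5.  Carriers
    beyond 1.5 x IQR of the carrier distribution are counted as outliers;
    variants with no carriers get an empty (NaN) summary.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(G.shape[1])]
    rows = []
    for j, vid in enumerate(variant_ids):
        carriers = G[:, j] >= CARRIER_MIN_DOSAGE
        for group, mask in (("carrier", carriers), ("non_carrier", ~carriers)):
            vals = y[mask]
            if vals.size == 0:
                rows.append(
                    {
                        "variant_id": vid,
                        "group": group,
                        "n": 0,
                        "min": np.nan,
                        "q1": np.nan,
                        "median": np.nan,
                        "q3": np.nan,
                        "max": np.nan,
                        "n_outliers": 0,
                        "empty": True,
                    }
                )
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            outliers = (vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)
            rows.append(
                {
                    "variant_id": vid,
                    "group": group,
                    "n": int(vals.size),
                    "min": float(vals.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(vals.max()),
                    "n_outliers": int(outliers.sum()),
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)
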