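"""Cis/trans scan orchestration, single-variant follow-up, Q-Q data.

The scan walks every eligible region x probe test pair, fits one null model
per probe (covariates do not change across regions, so the fit is cached and
reused) and records the kernel-test p-value.  Hits at the study-wide
threshold (P < 1e-14, strict) are followed up per variant by linear
regression, to separate genuinely collective signals from those a single
variant could explain on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import CpGIslandRegion, TestPair
from .skat import NullModel, WeightSpec, fit_null, single_variant_regression, skat_test

__all__ = [
    "ScanConfig",
    "ScanData",
    "run_scan",
    "followup_single_variants",
    "qq_points",
    "multi_timepoint_evaluation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    maf_cutoff: float = 0.05
    tier: str = "island_shore"
    cis_window_bp: int = 1_000_000
    p_threshold: float = 1e-14  # strict less-than
    replication_p: float = 0.01
    evaluation_p: float = 1e-7  # softer bound used across repeat time points
    weight_spec: WeightSpec = field(default_factory=WeightSpec)

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1 and 0 < self.replication_p < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.cis_window_bp <= 0:
            raise ValueError("cis window must be positive")


@dataclass
class ScanData:
    """Sample-aligned inputs for one dataset (one time point / cohort)."""

    dosages: np.ndarray  # samples x variants
    variant_ids: list
    variant_mafs: np.ndarray
    methylation: pd.DataFrame  # probes x samples
    covariates: np.ndarray | None  # samples x m

    def columns_for(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
        lookup = {v: j for j, v in enumerate(self.variant_ids)}
        present = [v for v in ids if v in lookup]
        cols = [lookup[v] for v in present]
        return self.dosages[:, cols], self.variant_mafs[cols], present


def run_scan(
    pairs: list[TestPair],
    regions: dict[str, CpGIslandRegion],
    data: ScanData,
    config: ScanConfig,
) -> pd.DataFrame:
    """One kernel test per (region, probe) pair; deterministic row order.

    Pairs whose probe is missing from the methylation matrix are skipped with
    a warning; regions with fewer than two variants at the cutoff are not
    tested.  The per-probe null model is fitted once and reused.
    """
    null_cache: dict[str, NullModel] = {}
    rows = []
    for pair in sorted(pairs, key=lambda p: (p.region_id, p.probe_id)):
        region = regions[pair.region_id]
        if not region.eligible:
            continue
        if pair.probe_id not in data.methylation.index:
            logger.warning("probe %s absent from methylation matrix; skipped", pair.probe_id)
            continue
        G, mafs, present = data.columns_for(region.variant_ids)
        if len(present) < 2:
            continue
        if pair.probe_id not in null_cache:
            y = data.methylation.loc[pair.probe_id].to_numpy(dtype=float)
            null_cache[pair.probe_id] = fit_null(y, data.covariates)
        null = null_cache[pair.probe_id]
        y = data.methylation.loc[pair.probe_id].to_numpy(dtype=float)
        res = skat_test(y, data.covariates, G, config.weight_spec, mafs=mafs, null=null)
        rows.append(
            {
                "region_id": pair.region_id,
                "tier": region.tier.value,
                "probe_id": pair.probe_id,
                "relation": pair.relation,
                "n_variants": res.n_variants,
                "p_value": res.p_value,
                "p_method": res.p_method,
                "passes_threshold": res.p_value < config.p_threshold,
            }
        )
    cols = [
        "region_id",
        "tier",
        "probe_id",
        "relation",
        "n_variants",
        "p_value",
        "p_method",
        "passes_threshold",
    ]
    return pd.DataFrame(rows, columns=cols)


def followup_single_variants(
    hit: pd.Series,
    regions: dict[str, CpGIslandRegion],
    data: ScanData,
    config: ScanConfig,
) -> tuple[pd.DataFrame, bool]:
    """Per-variant OLS effects for a passing pair.

    Returns the effect table and a drivers flag: True iff some single variant
    reaches the scan threshold alone, i.e. the signal is attributable to one
    variant rather than to the collapsed set.
    """
    region = regions[hit["region_id"]]
    G, _, present = data.columns_for(region.variant_ids)
    y = data.methylation.loc[hit["probe_id"]].to_numpy(dtype=float)
    rows = []
    for j, vid in enumerate(present):
        est = single_variant_regression(y, data.covariates, G[:, j])
        rows.append({"variant_id": vid, **{k: est[k] for k in ("beta", "se", "p")}})
    table = pd.DataFrame(rows)
    drivers = bool((table["p"] < config.p_threshold).any())
    return table, drivers


def qq_points(p_values: np.ndarray, floor: float = 1e-300) -> pd.DataFrame:
    """Expected vs observed -log10 p for a Q-Q plot.

    Observed values are sorted ascending; expected quantiles are
    -log10(i / (m + 1)).  Zero p-values are floored and flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    floored = p <= 0
    p = np.where(floored, floor, p)
    order = np.argsort(p)
    m = p.size
    return pd.DataFrame(
        {
            "expected": -np.log10(np.arange(1, m + 1) / (m + 1)),
            "observed": -np.log10(p[order]),
            "floored": floored[order],
        }
    )


def multi_timepoint_evaluation(
    hits: pd.DataFrame,
    regions: dict[str, CpGIslandRegion],
    datasets: dict[str, ScanData],
    config: ScanConfig,
) -> pd.DataFrame:
    """Re-test each hit in every other dataset with available variants only.

    Variants absent from a dataset are dropped, not replaced; a dataset with
    fewer than two available variants is marked untestable for that hit.
    """
    rows = []
    for _, hit in hits.iterrows():
        region = regions[hit["region_id"]]
        for name, data in datasets.items():
            G, mafs, present = data.columns_for(region.variant_ids)
            row = {
                "region_id": hit["region_id"],
                "probe_id": hit["probe_id"],
                "dataset": name,
                "n_variants": len(present),
            }
            if len(present) < 2 or hit["probe_id"] not in data.methylation.index:
                row.update({"p_value": np.nan, "testable": False})
            else:
                y = data.methylation.loc[hit["probe_id"]].to_numpy(dtype=float)
                res = skat_test(y, data.covariates, G, config.weight_spec, mafs=mafs)
                row.update(
                    {
                        "p_value": res.p_value,
                        "testable": True,
                        "passes_evaluation": res.p_value < config.evaluation_p,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)
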