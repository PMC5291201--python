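"""End-to-end orchestration: load, validate, preprocess, scan, follow up.

A single config drives the whole analysis (simulate -> preprocess -> region
building -> cis/trans scans -> single-variant follow-up -> conditional
re-tests -> leave-one-out), writing TSV tables, Q-Q data and a JSON summary
into the output directory together with the resolved config, so a run is
reproducible from its own artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .conditional import conditional_skat, prune_by_dprime
from .diagnostics import ld_prune, leave_one_out
from .preprocess import (
    align_samples,
    filter_variants,
    impute_missing_dosages,
    rank_inverse_normal,
)
from .regions import (
    Tier,
    build_regions,
    enumerate_pairs,
    region_table,
    tiered_eligibility,
)
from .scan import (
    ScanConfig,
    ScanData,
    followup_single_variants,
    multi_timepoint_evaluation,
    qq_points,
    run_scan,
)
from .skat import WeightSpec

__all__ = ["PipelineConfig", "validate_inputs", "run_end_to_end", "load_scan_data"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    islands_bed: str
    probes: str
    methylation: str
    covariates: str
    outdir: str
    known_mqtl: str | None = None
    probe_keep_list: str | None = None
    seed: int = 0
    maf_cutoff: float = 0.05
    tier: str = "island_shore"
    cis_window_bp: int = 1_000_000
    p_threshold: float = 1e-14
    exclusion_pad: int = 5000
    dprime_threshold: float = 0.8
    r2_prune_threshold: float = 0.8
    hwe_min: float = 5e-7
    maf_max: float = 0.05
    info_min: float = 0.8
    rank_normal: bool = True
    weights_a1: float = 1.0
    weights_a2: float = 25.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> list[str]:
        missing = []
        for key in ("vcf", "islands_bed", "probes", "methylation", "covariates"):
            p = getattr(self, key)
            if not Path(p).exists():
                missing.append(f"{key}: {p}")
        return missing

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            maf_cutoff=self.maf_cutoff,
            tier=self.tier,
            cis_window_bp=self.cis_window_bp,
            p_threshold=self.p_threshold,
            weight_spec=WeightSpec(self.weights_a1, self.weights_a2),
        )


def validate_inputs(config: PipelineConfig) -> dict:
    """Cross-check sample alignment, chromosome naming and probe coverage.

    Returns a report with ``fatal`` and ``warnings`` lists; an empty report
    means the inputs are fully consistent.
    """
    report: dict = {"fatal": [], "warnings": [], "dropped_by_intersection": []}
    missing = config.validate_paths()
    if missing:
        report["fatal"].extend(f"missing input {m}" for m in missing)
        return report
    variants, _, vcf_samples = mio.read_vcf(config.vcf)
    islands = mio.read_bed(config.islands_bed)
    probes = mio.read_probe_manifest(config.probes)
    meth = mio.read_matrix_tsv(config.methylation)
    cov = mio.read_covariates(config.covariates)

    vcf_chroms = set(variants["chrom"])
    bed_chroms = {i.chrom for i in islands}
    if vcf_chroms and bed_chroms:
        vcf_pref = any(c.startswith("chr") for c in vcf_chroms)
        bed_pref = any(c.startswith("chr") for c in bed_chroms)
        if vcf_pref != bed_pref:
            report["fatal"].append(
                "chromosome naming mismatch between VCF and BED "
                "(e.g. 'chr1' vs '1'); normalize one of them"
            )
    sets = {
        "vcf": list(vcf_samples),
        "methylation": list(meth.columns),
        "covariates": list(cov.index),
    }
    common = set(sets["vcf"]) & set(sets["methylation"]) & set(sets["covariates"])
    if not common:
        report["fatal"].append("no samples shared across VCF/methylation/covariates")
    for name, ids in sets.items():
        dropped = [s for s in ids if s not in common]
        if dropped:
            report["dropped_by_intersection"].append({name: dropped})
    if cov.isna().any().any():
        report["fatal"].append("covariate table contains missing values")
    unknown = set(probes["probe_id"]) - set(meth.index)
    if unknown:
        report["warnings"].append(
            f"{len(unknown)} manifest probes absent from the methylation matrix"
        )
    return report


def load_scan_data(config: PipelineConfig) -> tuple[ScanData, pd.DataFrame, list, pd.DataFrame]:
    """Read + QC inputs into a sample-aligned ScanData bundle.

    Order of operations: QC-filter variants, mean-impute missing dosages,
    intersect samples (genotype order), rank-normalize methylation per probe.
    Covariates enter every test's null design, so pre-residualized input is
    handled identically.
    """
    variants, dosages, vcf_samples = mio.read_vcf(config.vcf)
    islands = mio.read_bed(config.islands_bed)
    probes = mio.read_probe_manifest(config.probes)
    meth = mio.read_matrix_tsv(config.methylation)
    cov = mio.read_covariates(config.covariates)

    kept = filter_variants(variants, config.hwe_min, config.maf_max, config.info_min)
    cols = kept.index.to_numpy()
    dosages = impute_missing_dosages(dosages[:, cols])
    kept = kept.reset_index(drop=True)

    samples = align_samples(
        pd.Index(vcf_samples), pd.Index(meth.columns), cov.index
    )
    sample_pos = [vcf_samples.index(s) for s in samples]
    dosages = dosages[sample_pos, :]
    meth = meth[list(samples)]
    cov = cov.loc[list(samples)]
    if config.probe_keep_list is not None:
        keep_ids = set(
            pd.read_csv(config.probe_keep_list, sep="\t")["probe_id"]
        )
        probes = probes[probes["probe_id"].isin(keep_ids)].reset_index(drop=True)
    if config.rank_normal:
        meth = meth.apply(
            lambda row: pd.Series(rank_inverse_normal(row.to_numpy()), index=row.index),
            axis=1,
        )
    data = ScanData(
        dosages=dosages,
        variant_ids=kept["id"].tolist(),
        variant_mafs=kept["maf"].to_numpy(),
        methylation=meth,
        covariates=cov.to_numpy(dtype=float),
    )
    return data, kept, islands, probes


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle; returns the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if report["fatal"]:
        raise RuntimeError(f"input validation failed: {report['fatal']}")

    data, variants, islands, probes = load_scan_data(config)
    known = mio.read_known_mqtl(config.known_mqtl) if config.known_mqtl else None
    scan_cfg = config.scan_config()

    tier_counts = {
        "maf_05": tiered_eligibility(islands, variants, 0.05),
        "maf_01": tiered_eligibility(islands, variants, 0.01),
    }
    regions_list = build_regions(
        islands, variants, config.tier, config.maf_cutoff, known, config.exclusion_pad
    )
    regions = {r.region_id: r for r in regions_list}
    region_table({config.tier: regions_list}).to_csv(
        outdir / "regions.tsv", sep="\t", index=False
    )
    novel = [r for r in regions_list if not r.prior_mqtl_nearby]
    pairs = enumerate_pairs(novel, probes, config.cis_window_bp)
    cis_pairs = [p for p in pairs if p.relation == "cis"]
    trans_pairs = [p for p in pairs if p.relation == "trans"]

    cis = run_scan(cis_pairs, regions, data, scan_cfg)
    cis.to_csv(outdir / "scan_cis.tsv", sep="\t", index=False)
    trans = run_scan(trans_pairs, regions, data, scan_cfg)
    trans.to_csv(outdir / "scan_trans.tsv", sep="\t", index=False)
    if len(cis):
        qq_points(cis["p_value"].to_numpy()).to_csv(
            outdir / "qq_cis.tsv", sep="\t", index=False
        )

    hits = cis[cis["passes_threshold"]]
    followup_rows = []
    drivers = {}
    for _, hit in hits.iterrows():
        table, flag = followup_single_variants(hit, regions, data, scan_cfg)
        table.insert(0, "probe_id", hit["probe_id"])
        table.insert(0, "region_id", hit["region_id"])
        followup_rows.append(table)
        drivers[(hit["region_id"], hit["probe_id"])] = flag
    if followup_rows:
        pd.concat(followup_rows).to_csv(outdir / "followup.tsv", sep="\t", index=False)

    cond_rows = []
    if known is not None and len(known):
        cond_rows = _conditional_stage(config, data, regions_list, known, scan_cfg)
        pd.DataFrame(cond_rows).to_csv(outdir / "conditional.tsv", sep="\t", index=False)

    loo_tables = []
    for _, hit in hits.iterrows():
        region = regions[hit["region_id"]]
        G, mafs, present = data.columns_for(region.variant_ids)
        kept_idx = ld_prune(G, config.r2_prune_threshold)
        if len(kept_idx) < 3:
            continue
        y = data.methylation.loc[hit["probe_id"]].to_numpy(dtype=float)
        loo = leave_one_out(
            y,
            data.covariates,
            G[:, kept_idx],
            scan_cfg.weight_spec,
            [present[k] for k in kept_idx],
            mafs[kept_idx],
        )
        loo.insert(0, "probe_id", hit["probe_id"])
        loo.insert(0, "region_id", hit["region_id"])
        loo_tables.append(loo)
    if loo_tables:
        pd.concat(loo_tables).to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)

    summary = {
        "n_samples": data.dosages.shape[0],
        "n_variants_after_qc": len(variants),
        "tier_eligibility": tier_counts,
        "n_regions": len(regions_list),
        "n_eligible_regions": sum(r.eligible for r in regions_list),
        "n_conditional_regions": sum(r.prior_mqtl_nearby for r in regions_list),
        "n_cis_pairs": len(cis_pairs),
        "n_trans_pairs": len(trans_pairs),
        "n_cis_tested": len(cis),
        "n_trans_tested": len(trans),
        "n_cis_hits": int(len(hits)),
        "n_trans_hits": int(trans["passes_threshold"].sum()) if len(trans) else 0,
        "drivers_flags": {f"{k[0]}|{k[1]}": v for k, v in drivers.items()},
        "n_conditional_tested": len(cond_rows),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(asdict(config)))
    return summary


def _conditional_stage(config, data, regions_list, known, scan_cfg) -> list[dict]:
    """Re-test prior-mQTL regions conditioning on their index SNP(s)."""
    rows = []
    lookup = {v: j for j, v in enumerate(data.variant_ids)}
    for region in regions_list:
        if not region.prior_mqtl_nearby or not region.eligible:
            continue
        near = known[
            (known["chrom"] == region.island.chrom)
            & (known["pos"] - 1 >= region.island.start - config.exclusion_pad)
            & (known["pos"] - 1 < region.island.end + config.exclusion_pad)
        ]
        if not len(near):
            continue
        idx_cols = [lookup[s] for s in near["snp_id"] if s in lookup]
        if not idx_cols:
            logger.warning("index SNP(s) for %s not in genotype data", region.region_id)
            continue
        index_dosages = data.dosages[:, idx_cols]
        G, mafs, present = data.columns_for(
            [v for v in region.variant_ids if v not in set(near["snp_id"])]
        )
        retained = prune_by_dprime(
            G, present, index_dosages, config.dprime_threshold
        )
        keep = [present.index(v) for v in retained]
        probe_ids = near["probe_id"].dropna().unique().tolist()
        for probe_id in probe_ids:
            if probe_id not in data.methylation.index:
                continue
            row = {
                "region_id": region.region_id,
                "probe_id": probe_id,
                "index_snps": ",".join(near["snp_id"]),
                "n_variants_retained": len(retained),
            }
            if len(retained) < 2:
                row.update({"p_value": np.nan, "eligible": False})
            else:
                y = data.methylation.loc[probe_id].to_numpy(dtype=float)
                res = conditional_skat(
                    y,
                    data.covariates,
                    index_dosages,
                    G[:, keep],
                    scan_cfg.weight_spec,
                    mafs=mafs[keep],
                )
                row.update(
                    {
                        "p_value": res.p_value,
                        "eligible": True,
                        "passes_threshold": res.p_value < scan_cfg.p_threshold,
                    }
                )
            rows.append(row)
    return rows
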