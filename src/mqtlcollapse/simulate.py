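"""Coupled genotype / annotation / methylation simulator.

Emulates the inputs of an imputed-array methylation-QTL cohort: ~800 samples;
low-frequency variants (MAF <= 5%, with a rare tier <= 1%) arranged in LD
blocks around CpG islands; 450k-style probes placed near (and, for trans
checks, far from) the islands; rank-normal-scale methylation generated from

    y_i = alpha_0 + alpha' X_i + beta' G_i + eps_i,   eps ~ N(0, noise_sd^2)

with batch/cell-count-like covariates X.  Effects can be planted per region
in several modes (null, collapsed multi-variant with mixed signs, single
driver variant, a common index SNP plus an independent rare set, rare
variants that merely tag an index SNP, and a probe-overlapping rare variant),
and the full generative truth is recorded for parameter-recovery tests.

LD within a block uses a latent haplotype-pair model: every block has a
shared Bernoulli "backbone" haplotype indicator, minor alleles occur
(almost) only on backbone haplotypes, and rare mutation-style flips break
perfect coupling.  This makes the high-D' structure of tagging fixtures
exact by construction.  Blocks are mutually independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import folded_maf

__all__ = [
    "EffectSpec",
    "SimConfig",
    "SimTruth",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_annotations",
    "simulate_methylation",
    "simulate_dataset",
    "write_fixture_set",
]

MODES = {
    "null",
    "collapsed",
    "single_variant",
    "single_plus_collapsed",
    "tagged_only",
    "probe_overlap",
}


@dataclass(frozen=True)
class EffectSpec:
    """Planted generative effect for one island region."""

    region_index: int
    mode: str = "null"
    effect_sizes: tuple = ()
    index_snp_maf: float = 0.2
    index_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown effect mode {self.mode!r}")
        nz = [b for b in self.effect_sizes if b != 0]
        if self.mode == "null" and nz:
            raise ValueError("null mode requires all effect sizes to be zero")
        if self.mode == "collapsed" and len(nz) < 2:
            raise ValueError("collapsed mode requires >= 2 nonzero effects")


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions.

    Sample size, MAF range and variants-per-region mirror an imputed-array
    rare-variant mQTL cohort (~800 samples, MAF 1-5%, a handful of
    qualifying variants per island region).
    """

    n_samples: int = 800
    n_islands: int = 12
    island_length_range: tuple = (600, 2000)
    inter_island_gap_range: tuple = (60_000, 120_000)
    variants_per_region_range: tuple = (3, 8)
    maf_range: tuple = (0.01, 0.05)
    # rare variants are mutually near-independent by default; LD structure is
    # built explicitly by the tagging / probe-overlap scenarios and by
    # configs that raise the block size
    ld_block_size: int = 1
    probe_offset_range: tuple = (-400, 400)
    effect_scenarios: tuple = ()
    noise_sd: float = 1.0
    covariate_count: int = 3
    seed: int = 0
    # refresh only the methylation noise/covariates (same genotypes and
    # truth): emulates re-measuring the same cohort at another life stage
    noise_seed: int | None = None
    # per-haplotype flip probability breaking perfect LD; kept well below the
    # minor-allele frequency so stray off-backbone alleles do not swamp the
    # planted haplotype structure of rare variants
    mutation_rate: float = 5e-4
    n_trans_probes: int = 2

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie within (0, 0.5)")
        if self.island_length_range[0] <= 0:
            raise ValueError("island lengths must be positive")
        if self.inter_island_gap_range[0] <= 8000:
            raise ValueError(
                "inter-island gap must exceed 8 kb so shelf-expanded regions stay disjoint"
            )
        if 2 * self.n_samples * lo < 1:
            raise ValueError(
                f"n_samples={self.n_samples} too small to realize MAF {lo}: "
                "expected minor-allele count < 1"
            )
        for spec in self.effect_scenarios:
            if spec.region_index >= self.n_islands:
                raise ValueError(
                    f"effect scenario references region {spec.region_index} "
                    f"but only {self.n_islands} islands exist"
                )


@dataclass
class SimTruth:
    """Per-probe record of the generating model (for recovery tests)."""

    probes: dict = field(default_factory=dict)
    covariate_alpha: list = field(default_factory=list)
    noise_sd: float = 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "probes": self.probes,
                "covariate_alpha": self.covariate_alpha,
                "noise_sd": self.noise_sd,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            probes=d["probes"],
            covariate_alpha=d["covariate_alpha"],
            noise_sd=d["noise_sd"],
        )


@dataclass
class SimulatedDataset:
    config: SimConfig
    variants: pd.DataFrame  # id, chrom, pos, maf, block, region, info_score
    dosages: np.ndarray  # samples x variants
    sample_ids: list
    islands: pd.DataFrame  # chrom, start, end (0-based half-open)
    probes: pd.DataFrame  # probe_id, chrom, pos (1-based)
    methylation: pd.DataFrame  # probes x samples
    covariates: pd.DataFrame  # sample_id index, covariate columns
    truth: SimTruth


def _scenario_by_region(config: SimConfig) -> dict[int, EffectSpec]:
    out: dict[int, EffectSpec] = {}
    for spec in config.effect_scenarios:
        if spec.region_index in out:
            raise ValueError(f"duplicate scenario for region {spec.region_index}")
        out[spec.region_index] = spec
    return out


def _draw_block_haplotypes(
    rng: np.random.Generator,
    n_hap: int,
    target_mafs: np.ndarray,
    mutation_rate: float,
    backbone: np.ndarray | None = None,
) -> np.ndarray:
    """Haplotype alleles (n_hap x p) with minor alleles riding a shared backbone."""
    f = float(max(target_mafs.max() * 1.25, target_mafs.max() + 1e-6))
    f = min(f, 0.5)
    if backbone is None:
        backbone = rng.random(n_hap) < f
    else:
        f = max(float(backbone.mean()), 1e-6)
    p_on = np.clip(target_mafs / f, 0.0, 1.0)
    alleles = (rng.random((n_hap, target_mafs.size)) < p_on) & backbone[:, None]
    flips = rng.random(alleles.shape) < mutation_rate
    return alleles ^ flips


def _realize_variant(
    rng: np.random.Generator,
    n_hap: int,
    maf: float,
    mutation_rate: float,
    backbone: np.ndarray | None,
    max_tries: int = 100,
) -> np.ndarray:
    for _ in range(max_tries):
        hap = _draw_block_haplotypes(
            rng, n_hap, np.array([maf]), mutation_rate, backbone
        )[:, 0]
        if 0 < hap.sum() < n_hap:
            return hap
    raise RuntimeError(f"could not realize a polymorphic variant at MAF {maf}")


def simulate_genotypes(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Variant table + dosage matrix (+ per-region layout used downstream).

    Variants are placed inside each island's shelf-expanded footprint; LD
    blocks of ``ld_block_size`` share a latent backbone haplotype.  Regions
    whose scenario needs a common index SNP get one extra variant at
    ``index_snp_maf``; tagged_only regions reuse the index's minor-allele
    haplotype as the rare variants' backbone.  Monomorphic realizations are
    rejected and resampled.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scenarios = _scenario_by_region(config)
    n_hap = 2 * config.n_samples
    islands = _island_intervals(config)

    rows = []
    hap_cols = []
    layout: dict[int, dict] = {}
    vid = 0
    for k in range(config.n_islands):
        start, end = islands[k]
        spec = scenarios.get(k, EffectSpec(region_index=k))
        n_var = int(rng.integers(*config.variants_per_region_range, endpoint=True))
        if spec.effect_sizes:
            n_var = max(n_var, len(spec.effect_sizes))
        span_lo, span_hi = start - 4000 + 1, end + 4000 - 1
        positions = np.sort(
            rng.choice(np.arange(max(span_lo, 1), span_hi), size=n_var, replace=False)
        )
        mafs = rng.uniform(*config.maf_range, size=n_var)

        index_hap = None
        index_col = None
        region_cols: list[int] = []
        if spec.mode in {"single_plus_collapsed", "tagged_only"}:
            index_hap = _realize_variant(
                rng, n_hap, spec.index_snp_maf, config.mutation_rate, None
            )
            index_pos = int(rng.integers(max(span_lo, 1), span_hi))
            index_col = vid
            rows.append(
                {
                    "id": f"idx_{k:04d}",
                    "chrom": "chr1",
                    "pos": index_pos + 1,
                    "block": -1,
                    "region": k,
                    "info_score": float(rng.uniform(0.85, 1.0)),
                }
            )
            hap_cols.append(index_hap)
            vid += 1

        block_size = max(1, config.ld_block_size)
        for b0 in range(0, n_var, block_size):
            block_mafs = mafs[b0 : b0 + block_size]
            backbone = index_hap if spec.mode == "tagged_only" else None
            if backbone is None and block_size > 1:
                f = min(float(block_mafs.max() * 1.25 + 1e-6), 0.5)
                backbone = rng.random(n_hap) < f
            for j, maf in enumerate(block_mafs):
                bb = backbone if block_size > 1 or spec.mode == "tagged_only" else None
                hap = _realize_variant(rng, n_hap, maf, config.mutation_rate, bb)
                rows.append(
                    {
                        "id": f"var_{k:04d}_{b0 + j:03d}",
                        "chrom": "chr1",
                        "pos": int(positions[b0 + j]) + 1,
                        "block": b0 // block_size,
                        "region": k,
                        "info_score": float(rng.uniform(0.85, 1.0)),
                    }
                )
                hap_cols.append(hap)
                region_cols.append(vid)
                vid += 1

        overlap_col = None
        if spec.mode == "probe_overlap":
            # rare variant under the probe, coupled to the region's first block
            first_hap = hap_cols[region_cols[0]]
            overlap_hap = _realize_variant(
                rng,
                n_hap,
                float(np.clip(mafs[0], *config.maf_range)),
                config.mutation_rate,
                first_hap,
            )
            overlap_col = vid
            rows.append(
                {
                    "id": f"ovl_{k:04d}",
                    "chrom": "chr1",
                    "pos": int((start + end) // 2) + 1,  # placed at the probe site
                    "block": -2,
                    "region": k,
                    "info_score": float(rng.uniform(0.85, 1.0)),
                }
            )
            hap_cols.append(overlap_hap)
            vid += 1

        layout[k] = {
            "spec": spec,
            "region_cols": region_cols,
            "index_col": index_col,
            "overlap_col": overlap_col,
            "island": (start, end),
        }

    hap = np.stack(hap_cols, axis=1)  # n_hap x p
    dosages = (hap[0::2] + hap[1::2]).astype(float)  # samples x p
    variants = pd.DataFrame(rows)
    variants["maf"] = [folded_maf(dosages[:, j]) for j in range(dosages.shape[1])]
    zero = variants.index[variants["maf"] <= 0].tolist()
    if zero:
        raise RuntimeError(f"monomorphic variants after resampling: {zero}")
    variants["hwe_p"] = 1.0  # filled from genotypes by the reader; placeholder here
    return variants, dosages, layout


def _island_intervals(config: SimConfig) -> list[tuple[int, int]]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    islands = []
    pos = 10_000
    for _ in range(config.n_islands):
        gap = int(rng.integers(*config.inter_island_gap_range, endpoint=True))
        length = int(rng.integers(*config.island_length_range, endpoint=True))
        start = pos + gap
        islands.append((start, start + length))
        pos = start + length
    return islands


def simulate_annotations(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Island BED intervals and the probe manifest.

    One cis probe per island (at the island centre plus a small offset) and
    ``n_trans_probes`` probes on a second chromosome, exercising the trans
    relation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    islands = _island_intervals(config)
    bed = pd.DataFrame(
        [{"chrom": "chr1", "start": s, "end": e} for s, e in islands]
    )
    probes = []
    for k, (s, e) in enumerate(islands):
        offset = int(rng.integers(*config.probe_offset_range, endpoint=True))
        probes.append(
            {
                "probe_id": f"cg{k:08d}",
                "chrom": "chr1",
                "pos": max(1, (s + e) // 2 + offset + 1),
            }
        )
    for t in range(config.n_trans_probes):
        probes.append(
            {
                "probe_id": f"cg9{t:07d}",
                "chrom": "chr2",
                "pos": 1_000_000 + 50_000 * t + 1,
            }
        )
    return bed, pd.DataFrame(probes)


def simulate_methylation(
    dosages: np.ndarray,
    layout: dict,
    probes: pd.DataFrame,
    variants: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Methylation matrix (probes x samples), covariates, and the truth record.

    Each island's probe is generated from the linear model using that
    region's planted effect; trans probes and unplanted islands are null.
    """
    noise_seed = config.seed if config.noise_seed is None else config.noise_seed
    rng = np.random.default_rng(np.random.SeedSequence([noise_seed, 4]))
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # batch indicator plus cell-proportion-like continuous covariates
    cov_cols = {}
    m = config.covariate_count
    if m >= 1:
        cov_cols["batch"] = rng.integers(0, 2, size=n).astype(float)
    for j in range(1, m):
        cov_cols[f"cell_prop{j}"] = np.clip(
            rng.normal(0.3, 0.1, size=n), 0.0, 1.0
        )
    covariates = pd.DataFrame(cov_cols, index=pd.Index(sample_ids, name="sample_id"))
    alpha = rng.normal(0.0, 0.3, size=len(cov_cols))
    cov_effect = covariates.to_numpy() @ alpha if len(cov_cols) else np.zeros(n)

    truth = SimTruth(covariate_alpha=alpha.tolist(), noise_sd=config.noise_sd)
    meth_rows = {}
    island_probe_ids = [
        probes.iloc[k]["probe_id"] for k in range(config.n_islands)
    ]
    var_ids = variants["id"].tolist()
    for k in range(config.n_islands):
        info = layout[k]
        spec: EffectSpec = info["spec"]
        probe_id = island_probe_ids[k]
        g_effect = np.zeros(n)
        contrib: list[str] = []
        betas: list[float] = []
        if spec.mode in {"collapsed", "single_variant", "single_plus_collapsed"}:
            eff = np.asarray(spec.effect_sizes, dtype=float)
            cols = info["region_cols"][: eff.size]
            missing = eff.size - len(cols)
            if missing > 0:
                raise ValueError(
                    f"scenario for region {k} references {missing} variants beyond "
                    "those generated"
                )
            g_effect = g_effect + dosages[:, cols] @ eff
            contrib += [var_ids[c] for c in cols]
            betas += eff.tolist()
        if spec.mode in {"single_plus_collapsed", "tagged_only"}:
            c = info["index_col"]
            g_effect = g_effect + spec.index_beta * dosages[:, c]
            contrib.append(var_ids[c])
            betas.append(spec.index_beta)
        if spec.mode == "probe_overlap":
            c = info["overlap_col"]
            g_effect = g_effect + spec.index_beta * dosages[:, c]
            contrib.append(var_ids[c])
            betas.append(spec.index_beta)
        eps = rng.normal(0.0, config.noise_sd, size=n)
        meth_rows[probe_id] = cov_effect + g_effect + eps
        truth.probes[probe_id] = {
            "region": k,
            "mode": spec.mode,
            "variant_ids": contrib,
            "beta": betas,
        }
    for t in range(config.n_trans_probes):
        pid = f"cg9{t:07d}"
        meth_rows[pid] = cov_effect + rng.normal(0.0, config.noise_sd, size=n)
        truth.probes[pid] = {"region": -1, "mode": "null", "variant_ids": [], "beta": []}

    meth = pd.DataFrame.from_dict(meth_rows, orient="index", columns=sample_ids)
    meth.index.name = "probe_id"
    return meth, covariates, truth


def default_study_config(seed: int = 0, n_islands: int = 12) -> SimConfig:
    """The canonical synthetic cohort used by the analysis scripts.

    ~800 samples, one probe per island, rare-variant MAFs 1-5%, unit noise;
    one region per planted-effect mode and the remainder null.  Per-allele
    effects of ~0.7 SD (mixed signs) for collapsed sets and ~2 SD for the
    single-driver region are in line with the strong per-locus effects seen
    in methylation QTL mapping.
    """
    scenarios = (
        EffectSpec(0, "collapsed", (0.7, -0.7, 0.7, -0.7, 0.7)),
        EffectSpec(1, "single_variant", (2.0,)),
        EffectSpec(
            2,
            "single_plus_collapsed",
            (0.7, -0.7, 0.7, -0.7),
            index_snp_maf=0.2,
            index_beta=0.5,
        ),
        EffectSpec(3, "tagged_only", (), index_snp_maf=0.2, index_beta=0.8),
        EffectSpec(4, "probe_overlap", (), index_beta=1.5),
    )
    return SimConfig(n_islands=n_islands, seed=seed, effect_scenarios=scenarios)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genotypes, annotations, methylation, truth."""
    variants, dosages, layout = simulate_genotypes(config)
    islands, probes = simulate_annotations(config)
    meth, covariates, truth = simulate_methylation(
        dosages, layout, probes, variants, config
    )
    sample_ids = list(covariates.index)
    # fill HWE p-values from the realized hard calls
    from .preprocess import hwe_exact_pvalue

    hwe = []
    for j in range(dosages.shape[1]):
        g = np.rint(dosages[:, j]).astype(int)
        n_het = int(np.sum(g == 1))
        n_hom_minor = int(np.sum(g == 2))
        n_hom_major = int(np.sum(g == 0))
        hwe.append(hwe_exact_pvalue(n_het, n_hom_minor, n_hom_major))
    variants = variants.assign(hwe_p=hwe)
    return SimulatedDataset(
        config=config,
        variants=variants,
        dosages=dosages,
        sample_ids=sample_ids,
        islands=islands,
        probes=probes,
        methylation=meth,
        covariates=covariates,
        truth=truth,
    )


def write_fixture_set(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write VCF + BED + TSV + truth JSON; returns the path map.

    Output is deterministic for a fixed config (no timestamps), so identical
    configs produce byte-identical files.
    """
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "bed": outdir / "islands.bed",
        "probes": outdir / "probes.tsv",
        "methylation": outdir / "methylation.tsv",
        "covariates": outdir / "covariates.tsv",
        "truth": outdir / "truth.json",
    }
    mio.write_vcf(paths["vcf"], dataset.variants, dataset.dosages, dataset.sample_ids)
    mio.write_bed(paths["bed"], dataset.islands)
    dataset.probes.to_csv(paths["probes"], sep="\t", index=False)
    dataset.methylation.to_csv(paths["methylation"], sep="\t")
    dataset.covariates.to_csv(paths["covariates"], sep="\t")
    paths["truth"].write_text(dataset.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
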