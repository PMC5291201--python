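# mqtlcollapse

Region-collapsed rare-variant methylation-QTL analysis.

Single-variant mQTL mapping has little power for rare variants: a variant
carried by a handful of people cannot reach genome-wide significance on its
own. This package implements the complementary region-based approach:
low-frequency variants (MAF ≤ 5%, with a rare tier ≤ 1%) are collapsed over
CpG-island-anchored regions — the island itself, the island plus 2 kb
*shores*, or plus 4 kb *shelves* — and each region's variant set is tested
jointly against the methylation level of every CpG probe within ±1 Mb (cis)
or beyond (trans).

## The test

For a probe's (rank-normalized) methylation vector **y**, covariates *X* and
the region's dosage matrix *G* (n samples × p variants),

> yᵢ = α₀ + α′Xᵢ + β′Gᵢ + εᵢ

the per-variant effects βⱼ are treated as random with mean 0 and variance
wⱼ²τ, and H₀: τ = 0 is tested with the variance-component score statistic

> Q = r′ G W² G′ r / (2σ̂²),  W = diag(wⱼ),  wⱼ = Beta(MAFⱼ; a₁, a₂)

where r and σ̂² come from the covariate-only OLS fit and the weights
(default a₁ = 1, a₂ = 25) up-weight rarer variants. Under H₀, Q follows a
mixture Σᵢ λᵢχ²₁ with λ the eigenvalues of the covariate-projected weighted
kernel; tail probabilities are computed by characteristic-function inversion
(Imhof's method) with a moment-matched far-tail fallback, and cross-checked
against a permutation oracle. Because Q is quadratic in the per-variant
scores, variants pushing methylation in *opposite* directions do not cancel
— the reason this statistic is preferred over burden-style sums for mQTL.

Follow-up procedures included:

- **single-variant follow-up** — per-variant OLS to flag hits that a single
  variant could explain alone;
- **conditional analysis** — at loci with a known single-variant mQTL, the
  region is pruned of variants in high LD with the index SNP (D′ ≥ 0.8,
  two-locus EM from unphased genotypes) and re-tested with the index SNP as
  a covariate;
- **leave-one-out** — after greedy r² pruning, the test is re-run with each
  variant removed in turn;
- **probe-overlap conditioning** — re-test with a rare variant lying in the
  probe sequence as a covariate.

A synthetic-data generator produces coupled VCF/BED/TSV cohorts with planted
effects (and a JSON record of the generative truth), so the whole pipeline
is testable without any data download.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (800 samples, 12 CpG islands, rare variants at MAF 1–5%; regions 0–4
carry planted effects, the rest are null):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_scan_cis_trans.py
python analysis/03_followup_and_timepoints.py
python analysis/04_conditional_analysis.py
python analysis/05_leave_one_out.py
```

Script 02 prints:

```
cis scan: 144 tests, 2 below P < 1e-14:
  region_id   probe_id  n_variants      p_value
region_0000 cg00000000           6 1.982581e-20
region_0001 cg00000001           4 2.810770e-28
```

Both planted cis effects are recovered at the conservative study threshold
P < 1×10⁻¹⁴ while all null pairs stay above it. Script 03 separates them:

```
region_0000 x cg00000000: min single-variant p = 2.85e-10 -> collective effect
region_0001 x cg00000001: min single-variant p = 1.03e-35 -> single-variant driver
```

region_0000 is a genuinely collective signal (no single variant reaches the
threshold alone), region_0001 is driven by one variant. Script 04 shows the
conditional logic: the region whose rare set is independent of its index SNP
keeps a conditional p of 4.9×10⁻¹⁰, while the region that merely tags the
index loses all of its variants to D′ ≥ 0.8 pruning; conditioning on a
probe-overlapping rare variant collapses that region's apparent signal from
6.9×10⁻⁷ to 0.89. Script 05 confirms stability: the distributed effect keeps
−log10 p ≥ 14.3 (reference 19.7) under every single-variant removal, whereas
the single-driver region drops to 0.1 exactly when its driver is removed.

The same functionality is exposed as a CLI (`mqtlcollapse simulate`,
`validate`, `scan-cis`, `scan-trans`, `run-all`) over a YAML config; see
`mqtlcollapse --help`.

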