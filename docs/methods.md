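# Methods

## Model and statistic

Methylation at a probe is modelled as y = α₀ + α′X + β′G + ε with Gaussian
noise, where G holds dosages (0–2, fractional allowed) of the p variants
collapsed in one CpG-island-anchored region. The region test is the
variance-component score test of τ = 0 under βⱼ ~ (0, wⱼ²τ):

- Null model: OLS of y on [1, X]; residuals r, σ̂² = RSS/(n − rank). A
  near-zero σ̂² (outcome exactly linear in covariates) is an error, not a
  silent division.
- Weights: wⱼ = Beta-density(MAFⱼ; a₁, a₂), defaults (1, 25), the canonical
  choice that up-weights rarer variants smoothly; (1, 1) recovers flat
  weights. MAF is always recomputed from the analyzed sample's dosages and
  folded to (0, 0.5], never trusted from file metadata, so weighting is
  reproducible from inputs alone.
- Statistic: Q = ‖W G′r‖²/(2σ̂²) with G column-centered. The null spectrum
  is λ = eig(½·(PGW)′(PGW)) where P projects off the null design; under H₀,
  Q ~ Σλᵢχ²₁. Q and λ are only meaningful as a pair: any common rescaling
  convention yields the same tail probability.
- Degenerate columns: zero-variance genotype columns are dropped with a
  record; an entirely zero matrix is an error. Eigenvalues below 1e-10 ×
  λmax are discarded.

## Tail probabilities of the chi-square mixture

The primary route is numerical inversion of the characteristic function
(Imhof's integral). The integrand oscillates at frequency Q/2 with an
algebraically decaying envelope, so the tail beyond a cut point is evaluated
with the dedicated Fourier-weight quadrature (QAWF) after decomposing
sin(φ(u) − Qu/2); this keeps the inversion accurate (~1e-8 absolute) and
fast. An exactly-equal spectrum short-circuits to the closed-form scaled
chi-square.

Inversion is trusted when the result exceeds 1e-10 and the quadrature error
is below 1% of it. Beyond that — the deep tails where mQTL hits live
(p ~ 1e-20 and below) — the moment-matched non-central chi-square
approximation takes over: it matches Σλ, Σλ², and the skewness (or kurtosis
when the skewness match is infeasible), is monotone in Q, and is stable on
the log scale down to the floor of 1e-300. Every result records which
method produced it (`exact_quadform` / `moment_matched` / `permutation`).
The crossover point means p-values between roughly 1e-10 and 1e-14 come
from the approximation; the scan threshold comparison (strict `<` at
1e-14) therefore uses the approximation's monotone tail, which is the same
trade-off made by standard implementations of this test family.

## Permutation oracle

`permutation_pvalue` permutes the null-model residuals and recomputes the
*entire* statistic on each permuted vector — scores against the
covariate-projected genotypes and a re-estimated σ̂² — i.e. a full refit
under the permutation null (with intercept-only covariates both steps are
identities, since permutation preserves the mean and sum of squares). The
simpler scheme that freezes σ̂² and skips re-projection biases p by ~1–2%
at n = 200, which is detectable against a 100,000-permutation
Monte-Carlo band; the full refit is the correct oracle. Agreement is
asserted within 3 Monte-Carlo SEs on the log10 scale for p ∈ [0.001, 0.5].
Oracle instances use MAFs of 0.05–0.25 at n = 200 so minor-allele counts
(≥ ~10) are within the asymptotic regime of the analytic null; the
analytic approximation is known to be anticonservative for minor-allele
counts in the single digits, which at the study's n ≈ 800 corresponds to
MAFs well below the simulated 1% floor.

## Regions, tiers, windows

Intervals are 0-based half-open internally; VCF positions (1-based) and BED
records are converted at the boundary. Islands are expanded symmetrically
by 0 / 2,000 / 4,000 bp for the island / +shores / +shelves tiers, clamped
at coordinate 0. A region is eligible at a tier/cutoff iff ≥ 2 variants
fall inside the expanded interval with MAF ≤ cutoff; tier attribution for
the eligibility table is incremental (a region counts at the narrowest tier
at which it first becomes eligible). Cis means the probe coordinate lies
within 1 Mb (inclusive) of the expanded region's nearest edge on the same
chromosome; everything else is trans, so cis and trans exactly partition
regions × probes. Regions with a known single-variant mQTL within island
± 5 kb (configurable; some reports use ± 1 kb) are diverted from the novel
scan into the conditional analysis.

Scan thresholds: the discovery threshold is strict (`p < 1e-14`);
re-evaluation of hits in other time points or cohorts of the same design
uses a softer **upper** bound (`evaluation_p = 1e-7` by default) — the
evaluation criterion is "p below 1e-7", on the grounds that a repeated
signal combines with the discovery evidence. Trans scans default to the
islands+shores tier, the region definition that is most productive in cis.

## Preprocessing

Variant QC keeps hwe_p > 5e-7, MAF ≤ 0.05 and info score > 0.8 (missing
info scores — hard-called data — pass, with a log note). The HWE exact test
is the standard conditional enumeration over heterozygote counts. Missing
dosages are mean-imputed per variant (MAF recomputed afterwards).
Methylation is rank-inverse-normalized per probe with the rankit offset
c = 0.5 and average ranks for ties, then covariates are handled in the
test's null design. Normalize-then-residualize is the default order.
Because the covariates remain in the null design either way,
pre-residualizing the matrix and passing the same covariate set give
byte-identical p-values (asserted by test); the analysis sample is the
intersection of genotype, methylation and covariate sample ids, kept in
genotype order.

## Conditional analysis and LD

D′ is used for pruning rather than r² because the attainable range of r²
depends on the allele-frequency gap between a common index SNP and rare
variants, while D′ is normalized to [0, 1]. For hard calls, haplotype
frequencies come from the two-locus EM (50 iterations or Δ < 1e-8; only
the double-heterozygote cell is ambiguous); fractional dosages fall back to
the composite covariance estimator D = cov(g₁, g₂)/2, with the method
recorded. Pruning compares each region variant to the index SNP(s) only —
max D′ over indices when several exist — and removes at D′ ≥ 0.8
(inclusive). Conditioning appends the index dosages to the covariates; a
second pass for significant hits can condition on the full matrix of index
SNPs at the locus.

## Leave-one-out and outlier diagnostics

Variants are first pruned greedily in position order at r² ≥ 0.8 (the later
member of a correlated pair is dropped; deterministic and idempotent), so a
near-duplicate cannot mask its partner's removal. The kernel test is then
re-run leaving each retained variant out (requires ≥ 3, so every removal
leaves a testable pair), alongside the all-variants reference. Carrier
summaries (carrier = dosage ≥ 0.5) provide box-plot data with 1.5×IQR
outlier flags.

## Synthetic cohort

The generator emulates an imputed-array mQTL cohort at the analysis scale
(post-normalization), with defaults chosen once as the study conditions:
n = 800 samples, 12 islands (600–2,000 bp, gaps 60–120 kb so even
shelf-expanded regions stay disjoint), 3–8 variants per region at target
MAF 1–5%, one 450k-style probe near each island centre plus probes on a
second chromosome for the trans relation, unit noise SD, and three
batch/cell-proportion-like covariates with small coefficients.

Haplotypes use a latent backbone model: each LD block shares a Bernoulli
backbone indicator and minor alleles occur (almost) only on backbone
haplotypes, with rare mutation-style flips (5e-4 per haplotype, kept well
below the MAF so stray alleles do not erode the planted structure). This
makes the D′ truth of tagging fixtures exact by construction. Rare variants
default to mutually independent blocks (block size 1) — pairwise LD among
rare variants is weak in real data, and mixed-sign effects on near-copies
would cancel in y itself rather than in the test; LD is exercised
explicitly by the tagging/overlap scenarios and by configs that raise the
block size. Monomorphic realizations are rejected and resampled; a
configuration whose expected minor-allele count is below 1 is refused.

Planted modes per region: `null`; `collapsed` (≥ 2 nonzero mixed-sign βs,
default ±0.7 SD per allele — within the strong per-locus effect sizes seen
in methylation QTL studies); `single_variant` (one driver, default 2 SD);
`single_plus_collapsed` (common index SNP, MAF 0.2, plus an independent
rare set); `tagged_only` (rare variants riding the index haplotype, no
effect of their own); `probe_overlap` (a rare variant at the probe position,
coupled to the region's first variant, drives y). The full generative
record (contributing variants, β, α, noise SD, mode) is serialized as JSON.

What the generator does *not* emulate: realistic human LD maps, beta-value
distributions and probe chemistry, population structure or relatedness,
cell-type mixtures beyond generic covariates. Passing tests therefore
demonstrate the statistical machinery under its stated assumptions, not
robustness to those real-data complications.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to give tight Monte-Carlo
bands while keeping the whole suite fast: 2,000 null cohorts of n = 800 for
type-I error (99% binomial band at α = 0.05 is ±1.3 points), 50 instances ×
100,000 permutations for oracle agreement, a 12-island cohort (~144 cis
pairs) for planted-effect recovery. The trans bookkeeping identity is
evaluated at the reference scan's printed dimensions (8,701 × 294,905
regions × probes); the scan engine itself streams pairs and is independent
of scale.

## Known limitations

- No small-sample moment adjustment of the null distribution: for
  minor-allele counts in the single digits the analytic p is
  anticonservative; use the permutation route there.
- Quantitative traits only (linear kernel, identity link); no binary-trait
  variant, no optimal-rho combination with burden tests, no
  family/kinship adjustment (the intended design is cross-sectional).
- The conditional stage consumes a known index-SNP list; it does not
  discover index SNPs itself.
- Greedy r² pruning is a deterministic stand-in for external pruning tools
  whose window/step parameters are not part of this package's contract.
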