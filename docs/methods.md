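# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `grainvar`. Everything stated here is
computed by the package's tests or acceptance script; nothing is quoted
from external results.

## Trait definitions and units

Individual grain size is projected area in mm², a proxy for single-grain
mass. Per micro-plot bulk (300–500 grains): GSM = arithmetic mean area,
GSV = sample variance (n−1 denominator), P5/P95 = linear-interpolation
percentiles (Hyndman–Fan type 7). GSV therefore carries units mm⁴; where
coefficients of variation of dispersion are compared with those of means,
the SD scale √GSV is also emitted, since a variance mechanically varies
more than a mean. Yield components: GY (t/ha) and TKW (g) are expressed at
a notional 15% moisture (`wet = dry / 0.85`); GPM2 = GY·10⁵/TKW and
GPS = GPM2/SPM2 follow from unit conversion (1 t/ha = 100 g/m²).

The percentile convention and the variance denominator are deliberate
choices — the defining sources for such analyses rarely state them — and
both are fixed here so that every GSV value is reproducible.

## Mixed models

All mixed models have a single structured random term and are fitted by
profiled REML: with `V = σ²_e (I + λA)` and `A = UDU'`, rotating by `U'`
makes every GLS solve diagonal, and the REML log-likelihood

```
ℓ_R(λ) = −½ [ Σ log(1+λd_i) + (n−p) log σ̂²_e(λ) + log|X'W X| + (n−p) ]
```

is maximised over `log₁₀ λ ∈ [−8, 8]` by bounded Brent search (tolerance
1e-8, ≤ 200 evaluations), with the λ = 0 boundary checked explicitly so
null variance components are reported as exactly zero (truncation at the
bound, flagged). Variance components are non-negative by construction.

**Adjusted means.** `Y = μ + SB(random) + B(fixed) + G(fixed) + ε` per
environment. Identifiability uses sum-to-zero contrasts on blocks and
genotypes; the adjusted mean is `μ̂ + Ĝ_i`, a population-centred genotype
value, with its GLS standard error. Rank-deficient fixed designs raise a
non-estimability error naming the aliased genotype levels (pivoted QR).

**Heritability.** Two estimators mirror the two augmented layouts:

* *checks-replicated layout*: sub-block effects are BLUPs from a
  checks-only model (`μ + SB(random) + B + G_check`); all observations are
  corrected for them and a blocks-fixed, genotype-random REML fit yields
  σ²_G, σ²_ε.
* *two-step unreplicated layout*: the checks-only model estimates both
  sub-block BLUPs and block effects; both are subtracted everywhere and
  `Ycorr = μ + G(random) + ε` is fitted.

H² = σ²_G/(σ²_G+σ²_ε) on a per-plot basis, with no replication divisor:
most entries are unreplicated, so the plot residual is the natural error
unit. The two-step estimator is unbiased against a one-step oracle but
carries the step-1 estimation noise of order σ_e/√(check plots per block)
into singleton genotypes; with few checks this inflates per-dataset H²
spread (quantified in the test suite).

## Association scan

EMMAX/P3D scheme: per chromosome, λ = σ²_g/σ²_e is estimated once by REML
under the no-marker null with the LOCO kinship (VanRaden,
`K = WW'/(2Σp(1−p))` over all markers *not* on the tested chromosome,
jittered by 1e-8 on the diagonal before eigen-decomposition); each marker
is then tested by GLS at fixed λ with a 1-df Wald t-test
(df = n − 2), LOD = −log10(p), threshold strictly > 3 (configurable).
Effects are reported for the minor allele. Exact per-marker REML is
available behind `method="exact"` and agrees closely at realistic sizes.
No principal-component covariates are used: kinship is the only structure
correction. QC removes markers with missingness > 0.10 or MAF < 0.05
(the MAF rule is a below-threshold removal) and monomorphic markers;
missing dosages are replaced by the marker mean — a deterministic,
LD-agnostic imputation that is accurate at the <10% missingness QC admits.

## QTL intervals

* **Critical LD**: r² of random inter-chromosomal ("unlinked") marker
  pairs; the default statistic is the empirical 95th percentile, with a
  parametric variant (normal 95th percentile of √r², squared back) behind
  a flag. The choice between them is a documented default, not an assertion
  about any reference implementation.
* **Pruning**: greedy left-to-right within chromosome, ascending bp;
  among retained markers no pair has r² > 0.9. The scan order matters and
  is fixed so retained sets are reproducible.
* **Blocks**: average-linkage hierarchical clustering of significant SNPs
  at distance 1 − r², dendrogram cut at 1 − critical LD; clusters never
  span chromosomes (a QTL is a chromosomal interval).
* **Decay**: the Hill–Weir drift expectation
  `E[r²] = [(10+C)/((2+C)(11+C))]·[1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]`
  with `C = ρd` is fitted genome-wide to sampled intra-chromosomal pairs
  by bounded least squares; the extension distance d* solves
  `E[r²](d*) = critical LD` by bisection (|residual| < 1e-6), flagged
  infinite when the curve never crosses.
* **QTL**: blocks extended by d* on both sides (clipped to chromosome
  bounds), overlapping intervals merged; peak SNP = member with maximum
  LOD; sizes in Mb. Candidate regions are seeded by *every* significant
  SNP — a deterministic replacement for any visual pre-screening step.

## Classification and partitioning

Within an environment, a GSV QTL is **driven** iff at least one
significant yield-component SNP (SPM2, GPS, GPM2, TKW, GY) lies inside its
extended interval or among its members; otherwise **specific**. Across
environments, two QTL are **common** iff they share at least one
significant GSV SNP. The two rules differ on purpose: interval overlap
asks about pleiotropy at a locus; shared SNPs ask about replication of the
same association.

Per QTL one peak SNP is kept — maximum |minor-allele effect|, ties broken
by higher LOD then lower bp (a max-LOD rule is selectable). Adjusted GSV
is regressed on the peak dosages of all / specific-only / driven-only QTL
(collinear columns dropped by pivoted QR with a warning); r²_opt comes
from forward selection minimising Gaussian AIC
(`n log(RSS/n) + 2(k+1)`), stopping when no addition lowers AIC.
Forward-only search keeps the selection deterministic; under pure noise
AIC still admits a candidate whenever its t² > 2, so near-empty selections
are only guaranteed for small candidate sets.

## Synthetic data generator

The generator emulates the study conditions the analysis assumes, not crop
physiology.

**Genotypes** — founder-mosaic model: per chromosome, founder haplotypes
are a latent AR(1) Gaussian field (correlation `exp(−d·founder_ld_rate)`,
default rate 1e-7/bp) thresholded at each marker's allele frequency
(U(0.05, 0.95)); each individual's two haplotypes are founder mosaics with
Poisson(recomb_rate·L) breakpoints (default 2e-7/bp, L = 600 Mb,
30 founders). This yields r² ≈ 0.3 below 1 Mb decaying to background by
~10 Mb — realistic for a diverse inbred panel — while staying seed-stable
and fast. Chosen over coalescent simulation because downstream stages need
LD structure, not demography. 1% of calls are set missing.

**Trial** — per environment, 4 blocks × 2 sub-blocks; checks (default 4)
replicated in every sub-block, all other entries once, assigned
round-robin after a seeded shuffle. Defaults are one diverse-panel trial:
300 genotypes, two environments (well-watered; water-deficit with lower
spike density, grain number and grain size).

**Plot traits** (defaults calibrated to field-typical wheat: SPM2 ≈ 520,
GPS ≈ 34, area ≈ 17 mm², TKW ≈ 45 g, GY ≈ 7–8 t/ha):

```
SPM2 = 520 + env + g_SPM2 + subblock + N(0, 25)
GPS  = 34 + env + g_GPS − 0.5·(SPM2 − base)·34/520 + subblock + N(0, 1.5)
GPM2 = SPM2·GPS
μ_area = 17 + env − γ·(GPM2 − ref) + g_TKW + subblock + N(0, 0.35),  γ = 3e-4
```

The γ term is the source-limitation trade-off: more grains per m² → smaller
mean grain, which propagates to TKW and produces the emergent negative
GPM2–TKW correlation. Per-trait QTL (default 4 each for SPM2, GPS,
TKW-potential, GSV) are drawn among markers with MAF ≥ 0.15 separated by
≥ 30 Mb, with effects ~N(0, per-trait SD); pleiotropy groups share a locus
and a common standardised effect. Non-positive SPM2/GPS are clipped at
floors (50, 5) and counted.

**Individual grains** — two-level mixture: spike class (secondary-tiller
proportion 0.15 + 0.0008·(SPM2 − base), capped at 0.6; secondary mean
×0.90) then grain position (30% distal, mean ×0.85), class means scaled so
the mixture mean equals μ_area. Within-class SD =
2.0·(μ_area/17)·exp(g_GSV): dispersion scales with the mean (large-grained
genotypes vary more, giving the positive TKW–GSV correlation) and the
dispersion loci act multiplicatively on it without touching any mean.
An upper-tail cap at μ + (2.6 − 0.004·(SPM2 − base))·σ is applied as soft
truncation (resampling above the cap, floor 0.8σ), so a denser canopy
trims the largest grains — the mechanism behind the emergent negative
SPM2–GSV correlation. Draws below 0.5 mm² are also resampled, keeping
areas positive. The within-spike shrink factors and cap coefficients are
free parameters with no canonical values; they were chosen once to produce
these emergent signs at the defaults and are not otherwise fitted.

**Grain mass** — dry mass (mg) = 2.25·area + N(0, 1.15) per grain
(per-grain R² ≈ 0.8); TKW = mean grain mass expressed at 15% moisture;
GY = GPM2·TKW/10⁵ exactly, so deriving GPM2/GPS back from (GY, SPM2, TKW)
is an identity.

**Truth record** — planted loci with effects, per-genotype genetic values,
per-sub-block spatial effects, and variance components, for recovery
tests.

**What the generator does not emulate**: genotype-by-environment
interaction beyond additive shifts (environments draw independent spatial
effects only), crop phenology and weather, selection or family structure
in the panel (mosaic relatedness is random), measurement-device artefacts,
and any size gate on very small grains. Passing tests therefore show the
chain recovers the structure it models — trade-offs, dispersion loci,
spatial effects — not that real field data meet those assumptions.

## Problem sizes and determinism

Default scale (300 genotypes, 3 × 1000 markers, 2 environments) runs the
full chain in well under a minute on one CPU; the test suite's heavier
property checks use 20–200 replicates at reduced marker counts, sizes
chosen so each check retains its statistical meaning. All randomness flows
from one integer seed through named substreams
(`SeedSequence([seed, stream])`); equal seeds give byte-identical reports
(the report echoes the configuration minus the output path).

## Known limitations

* Mean-dosage imputation ignores LD; fine below the 10% missingness QC
  bound, not a general-purpose imputer.
* The Fisher-z comparison of correlations assumes independent samples,
  while environments share genotypes; p-values for that comparison are
  anti-conservative to an unquantified degree.
* The single-λ-per-chromosome (P3D) approximation understates uncertainty
  slightly relative to exact per-marker REML; the exact path exists but is
  ~m times slower.
* Driven/specific classification is positional, not a formal pleiotropy
  test; with long extension distances chance colocalisation grows with
  QTL density, which is why recovery guarantees hold for well-separated
  planted loci.
* H² has no replication divisor and is not comparable to entry-mean
  heritabilities from replicated designs.
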