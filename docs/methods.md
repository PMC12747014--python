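# Methods

## Study design

The package implements a two-step Mendelian randomization (MR) mediation
design. Three causal quantities are estimated from GWAS summary statistics
measured in non-overlapping samples:

* **β₀** — total effect of the exposure on the outcome (univariable MR);
* **β₁** — effect of the exposure on a candidate mediator (univariable MR
  with the exposure's instruments);
* **β₂** — effect of the mediator on the outcome *adjusted for the
  exposure* (multivariable MR on the union of the exposure's and the
  mediator's instruments).

The indirect (mediated) effect is β₁β₂, the direct effect is β₀ − β₁β₂, and
the proportion mediated is β₁β₂/β₀. All traits are treated as standardized
(SD units), so effects are unit-free.

Identifying assumptions are the usual instrumental-variable triple —
relevance, independence from confounders, and exclusion (no effect on the
outcome except through the exposure) — plus, for the mediation
decomposition, linearity, no exposure–mediator interaction, and
independence of the three estimates' errors (justified by the separate GWAS
samples; the covariance terms a shared-sample design would need are not
modelled).

## Instrument selection

1. **Significance**: p < 5×10⁻⁸. When fewer than `min_snps` (default 3, the
   minimum for MR-Egger) pass, the threshold relaxes to 1×10⁻⁵ and the
   selection is flagged `fallback_used`.
2. **Independence**: greedy LD clumping. Candidates are visited by
   ascending p (ties broken by chromosome, position, SNP id, which makes
   the output invariant to input order); a SNP is kept iff its r² with
   every already-kept SNP within 10,000 kb is below 0.01. SNPs on different
   chromosomes are never mutually exclusive; SNPs with unknown positions
   fall back to the r² entry alone.
3. **Strength**: F = (β/se)² ≥ 10. The variance-explained form
   F = (n−2)R²/(1−R²) with R² = 2·eaf(1−eaf)β² is provided as a documented
   variant (`f_statistic_r2`) but is not the default, because per-SNP
   sample sizes are frequently absent from mediator GWAS.

Every stage partitions its candidates into kept and dropped (with reasons),
and the pipeline manifest records the counts, so candidate conservation can
be audited.

## Harmonization

Outcome effects are aligned to the exposure's effect allele through the
standard ladder: direct match → allele swap (negate β, complement the
frequency) → strand flip (complement bases) → flip+swap; anything else is
excluded as `allele_mismatch`, never silently kept. Palindromic SNPs (A/T,
C/G) are oriented by allele frequency when informative and excluded as
`ambiguous_palindrome` when either trait's frequency is within
`palindrome_eaf_window` (default 0.08, i.e. eaf ∈ [0.42, 0.58]) of 0.5 or
missing. The window default matches common two-sample-MR practice.

## Estimators

With harmonized pairs (γⱼ, Γⱼ) and outcome variances σⱼ²:

* **IVW**: β̂ = Σwγⱼ Γⱼ / Σwγⱼ², w = 1/σⱼ². Fixed-effect
  se = (Σγⱼ²/σⱼ²)^−½; the default multiplicative random-effects flavor
  multiplies it by max(1, √(Q/(n−1))) so that heterogeneity widens but never
  narrows the interval. A single instrument reduces to the Wald ratio with
  the fixed se.
* **MR-Egger**: weighted regression of Γ on γ *with* intercept, after
  orienting all γⱼ > 0. SE scaling max(1, √(RSSw/(n−2))); p-values from t
  with n−2 df (all other estimators use two-sided normal p-values).
* **Weighted median**: ratios ordered, weights ∝ inverse first-order ratio
  variance (γⱼ²/σⱼ²); the estimate interpolates the weighted empirical CDF
  at 0.5 using standardized cumulative weights sⱼ = (cumⱼ − wⱼ/2)/Σw.
* **Modes**: Gaussian-kernel density of the ratios with bandwidth
  φ·0.9·min(sd, IQR/1.349)·n^(−1/5) (φ default 1), evaluated on a fixed
  512-point grid spanning the ratios ± 3 bandwidths; the estimate is the
  grid argmax. `simple` weights ratios equally, `weighted` by inverse
  variance. If all ratios coincide the bandwidth is zero and the common
  ratio is returned.
* **Bootstrap SEs** (median and modes): parametric — each (γⱼ, Γⱼ) is
  redrawn from independent normals at its standard errors, `n_boot`
  (default 1000) times, seeded; results are bit-for-bit reproducible for a
  fixed seed.
* **Multivariable IVW**: WLS of Γ on the (n×K) exposure-effect matrix, no
  intercept, weights 1/σⱼ²; requires n > K and a well-conditioned weighted
  design (condition number ≤ 1e8, otherwise a collinearity error). The
  mediator's coefficient is β₂.

Normal-approximation 95% CIs (β ± 1.96 se) are used everywhere, including
for the Egger coefficients whose p-values are t-based; the CI/ p-value
mismatch there is at most a few percent for the instrument counts this
design targets and is accepted for uniformity of the result records.

## Sensitivity

Cochran's Q uses the same first-order ratio weights as IVW (so Q computed
on ratios equals the weighted residual sum of squares of the IVW
regression), df = n−1, I² = max(0, (Q−df)/Q). The pleiotropy test is the
Egger intercept. Leave-one-out recomputes IVW on each n−1 subset. Q is
evaluated against the headline IVW estimate.

## Mediation arithmetic

`two_step_mediation` enforces the decomposition identities exactly
(indirect = β₁β₂ by definition; direct = β₀ − indirect; proportion =
indirect/β₀). The proportion SE uses the full three-term delta method

    se(p)² = (β₂/β₀)² se₁² + (β₁/β₀)² se₂² + (β₁β₂/β₀²)² se₀²

including the total-effect term — the two-term version visibly understates
the interval width for the effect sizes this design works at. At β₁ = 0 or
β₂ = 0 the surviving product term is used. Sign-inconsistent rows (indirect
and total effects of opposite signs) are flagged with a warning and a
negative proportion, not suppressed. The delta SE is validated in the test
suite against a seeded Monte-Carlo propagation; because a ratio of normals
has no finite variance, the Monte-Carlo oracle uses the central-68%
half-width, the normal-consistent scale.

## Screening pipeline

For each candidate mediator: step 1 (β₁) uses the exposure's instruments;
the reverse-MR guard estimates mediator → exposure from the *mediator's*
instruments and disqualifies the mediator when that estimate is significant
at α; step 2 (β₂) is multivariable IVW on the union of both instrument
sets. A mediator/outcome pair qualifies when both step p-values are below α
(default 0.05) and the reverse test is not; mediation rows are emitted only
for outcomes whose total effect is itself significant. Per-mediator
failures are isolated and recorded, never fatal. Multiplicity handling is
`none` by default (mirroring screens that report nominal significance);
Benjamini–Hochberg FDR across mediators (`mtc="bh_fdr"`) is available and
recommended for wide panels. The screen's internal steps use the headline
IVW only; the full estimator battery is available per pair via
`run_total_effect`.

Note that the reverse-MR guard is itself a nominal-α test: with α = 0.05 a
genuinely unidirectional mediator is falsely disqualified in about 5% of
datasets. This is inherent to the design, not a defect.

## Synthetic data

The generator simulates summary statistics directly — no individual-level
genotypes — since two-sample MR consumes nothing else. True per-SNP
effects: γⱼ ~ N(0, `gamma_sd`²) on `n_causal_exp` exposure SNPs; mediator
effects β₁γⱼ plus δⱼ ~ N(0, `delta_sd`²) on a disjoint set of
`n_causal_med` mediator-specific SNPs; outcome effects
(direct + β₁β₂)γⱼ + β₂δⱼ, plus optional pleiotropy
~ N(`directional_pleiotropy`, `pleiotropy_sd`²) on exposure SNPs. The
mediator-specific SNPs are essential: if every instrument's exposure and
mediator effects were exactly proportional, the multivariable regression
separating direct and mediated paths would be unidentified. Observed betas
add noise with the standardized-trait standard error
seⱼ = 1/√(2n·eafⱼ(1−eafⱼ)); p-values are two-sided normal, floored at
1e-300.

Defaults are the study conditions used throughout the tests: 200 SNPs, 50
causal per trait, sample sizes 50,000 per GWAS, eaf ~ U(0.05, 0.95),
`gamma_sd` = 0.05 (yielding a realistic mix of genome-wide-significant and
sub-threshold instruments at n = 50,000), `delta_sd` = 0.1, β₁ = 0.3,
β₂ = 0.4, direct = 0.2 — hence true total effect 0.32 and true proportion
mediated 0.375.

LD is block-exchangeable (constant r² inside blocks, zero between; blocks
placed far apart across chromosomes) — sufficient to exercise the clumping
logic, with no claim of realism; in particular the *noise* of SNPs within
an LD block is still drawn independently. Other real-data features the
generator does not emulate: winner's curse in the source GWAS, allele
coding errors and strand ambiguity (all alleles are A/G), non-normal effect
size distributions, and sample overlap. Passing recovery tests therefore
demonstrate the estimators' and pipeline's correctness under the stated
model, not robustness to those artefacts. `reverse_mediation=True` swaps
the exposure/mediator true-effect vectors so the trait labelled mediator is
the upstream cause — the scenario the reverse-MR guard must catch.

## Problem sizes in the test suite

Stochastic checks use 500 replicates for null calibration (50 instruments
each), 200 replicates for mediated-proportion recovery at the default
scenario, and 20 replicates of a 1-causal + 4-null mediator panel; the
whole suite runs in well under a minute on one CPU. Bootstrap counts inside
the pipeline tests are reduced to 100–200 (the point estimates under test
do not depend on `n_boot`).

## Known limitations

* No correlated-instrument IVW; clumping is assumed to have removed LD.
* No MR-PRESSO outlier removal, Steiger filtering, or
  contamination-mixture models.
* Proportion CIs are symmetric normal intervals; for weak total effects
  the proportion's sampling distribution is heavy-tailed and the delta
  interval degrades (flagged indirectly by sign-inconsistency warnings).
* The reverse-MR guard can be confounded when the exposure's effect on the
  mediator is strong enough that exposure SNPs enter the mediator's
  instrument set; with a high-powered exposure GWAS this inflates the
  reverse estimate's denominator only mildly, but it is not a Steiger
  orientation test.
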