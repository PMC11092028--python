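# Methods

## Model and assumptions

Two-sample MR treats SNPs as instrumental variables for an exposure:
each instrument must be associated with the exposure (relevance),
independent of exposure-outcome confounders, and affect the outcome only
through the exposure (exclusion restriction). All computation is at the
summary-statistic level: per-SNP effect estimates, standard errors,
p-values, allele frequencies and sample sizes from two non-overlapping
GWAS. Effects on binary traits are log-odds; continuous traits are in
SD units. The per-SNP Wald ratio β̂ᵧ/β̂ₓ estimates the causal effect θ;
the estimators differ in how they pool ratios when some instruments are
invalid.

## Harmonization

Exposure and outcome tables are merged on SNP id and the outcome effect
re-signed to the exposure's effect allele. Strand-complement codings of
non-palindromic SNPs are normalized before comparison. Palindromic (A/T,
C/G) SNPs cannot be strand-resolved from alleles: they are dropped when
either allele frequency is missing or within ±0.08 of 0.5 (configurable),
and otherwise oriented by frequency (a flip is inferred when the two
frequencies fall on opposite sides of 0.5). This conservative default
trades a few instruments for protection against strand ambiguity.
Indels and proxy-SNP lookup are out of scope.

## Instrument selection

The selection order is fixed: p-value threshold → LD clumping →
F-statistic screen → minimum-SNP rule. Clumping is greedy by ascending
p (ties broken by chromosome, position, then SNP id for determinism):
the best remaining SNP indexes a clump and removes every other SNP on
the same chromosome within ±10,000 kb with r² ≥ 0.001 against it. SNPs
absent from the LD reference are dropped with a warning, mirroring how
reference-panel clumping behaves.

Per-SNP explained variance uses 2·eaf·(1−eaf)·β² for continuous traits
with a known frequency (standardized-genotype, standardized-trait
approximation) and z²/(z²+N−2) otherwise, including binary traits on
the log-odds scale. The instrument-strength screen applies
F = R²(N−2)/(1−R²) per SNP — the K-instrument formula
[R²/K × (N−K−1)/(1−R²)] evaluated at K=1 — which reduces exactly to
z² = β²/SE², the fallback used when the source GWAS lacks N. Evaluating
the formula with K set to the instrument count would divide each SNP's
F by K and, at the lenient inclusion threshold used for microbiome
exposures (p < 1×10⁻⁵, i.e. |z| ≳ 4.4), would discard essentially every
instrument once K ≥ 3; the per-SNP convention is the one under which
"remove F < 10" is a meaningful weak-instrument rule.

## Estimators

* **IVW** — weighted mean of ratios with weights (β̂ₓ/σᵧ)², identical to
  WLS of β̂ᵧ on β̂ₓ through the origin with weights 1/σᵧ². The default is
  a multiplicative random-effects model: SE × √max(1, Q/(n−1)). The
  inflation never deflates below the fixed-effect SE; p-values are
  normal. A single instrument degrades to the Wald ratio.
* **MR-Egger** — the same regression with a free intercept, instruments
  oriented so every β̂ₓ > 0. The slope is consistent under InSIDE
  (pleiotropy independent of instrument strength) even when all
  instruments are invalid; the intercept estimates the mean directional
  pleiotropic effect per instrument and its p-value (t, n−2 df) is the
  pleiotropy test. Same multiplicative SE inflation.
* **Weighted median** — the interpolated weighted median of ratios with
  cumulative-weight convention sᵢ = (Σ_{j≤i}wⱼ − wᵢ/2)/Σw; consistent
  when valid instruments carry ≥50% of the weight. SE by parametric
  bootstrap: ratios resampled from N(ratioᵢ, σᵧᵢ/|β̂ₓᵢ|), weights fixed,
  1000 draws, seeded.
* **Weighted mode** — argmax of an inverse-variance-weighted Gaussian
  KDE of the ratios on a 512-point grid spanning the ratio range ±3
  bandwidths; bandwidth φ × 0.9·min(sd, IQR/1.349)·n^(−1/5) with φ = 1
  by default. Bootstrap SE as for the median. Degenerate case (all
  ratios equal → zero bandwidth) returns the common ratio.

All bootstrap SEs are exactly reproducible given the seed, which is a
required parameter of the public API.

## Sensitivity suite

* **Cochran's Q** with the IVW weights; df = n−1. Pairs with Q p < 0.05
  are excluded from reporting (strictly below). Note that these weights
  ignore exposure-side noise, so Q over-rejects somewhat when
  instruments are weak relative to N — visible in simulation as an
  exclusion rate slightly above the nominal 5%.
* **Egger intercept**: exclusion when intercept p < 0.05 (strict).
* **MR-PRESSO**: observed statistic RSS = Σ wᵢ(β̂ᵧᵢ − θ̂₋ᵢβ̂ₓᵢ)² with
  leave-one-out IVW predictions and wᵢ = 1/σᵧᵢ²; the null distribution
  comes from 1000 parametric simulations (β̂ₓ* ~ N(β̂ₓᵢ, σₓᵢ),
  β̂ᵧ* ~ N(θ̂₋ᵢβ̂ₓᵢ, σᵧᵢ)) with leave-one-out slopes recomputed inside
  each draw; +1/(n+1) smoothing on all empirical p-values. Per-SNP
  outlier p-values are Bonferroni-adjusted and flagged at α = 0.05. The
  distortion test compares the estimate shift after outlier removal to
  removing equally many random SNPs (500 draws). Requires ≥4
  instruments.
* **Steiger**: the instruments' summed R² on the exposure versus the
  outcome; the p-value is a two-sample z-test on the difference of
  Fisher-z transformed √R². An exact tie reports `correct = False`.
* **BH-FDR** (statsmodels' `fdr_bh` behind the module surface), applied
  after sensitivity exclusions, within one family per outcome (all
  exposures of a panel against that outcome); both thresholds of the
  classification rule are strict: significant (q < 0.05), suggestive
  (p < 0.05, q ≥ 0.05), null otherwise. Exclusion-before-FDR is a
  deliberate ordering choice; excluded pairs are logged with reasons so
  the alternative ordering can be audited.

## Mediation

Two-step MR with the product-of-coefficients decomposition: β₁
(exposure→mediator) and β₃ (exposure→outcome) use the exposure's
instruments at the lenient threshold; β₂ (mediator→outcome) uses the
mediator's own genome-wide instruments in a univariable MR — a known
limitation relative to multivariable MR, which would estimate β₂
conditional on the exposure. Triples are screened to those with all
three legs at least suggestive (p < 0.05). The proportion mediated is
β₁β₂/β₃; its CI comes from a parametric bootstrap (10,000 draws, all
three betas resampled, β₃ included, since the ratio distribution is
skewed), widened if necessary to contain the plug-in point estimate;
the p-value is the Sobel normal test on β₁β₂. A first-order delta
interval is available via `method="delta"`. Proportions outside [−1, 2]
are reported but flagged as inconsistent mediation.

## LDSC

Univariate fits regress z² on the LD score ℓ with two-step weighting
(1/ℓ, then 1/(ℓ·2·E[z²]²) from the first pass); h² = slope·M/N and the
intercept absorbs confounding (≈1 in its absence). The bivariate fit
regresses z₁z₂ on ℓ; gencov = slope·M/√(N₁N₂) and rg = gencov/√(h₁²h₂²),
undefined (flagged) when either heritability estimate is non-positive.
The SE is a delete-one block jackknife over 200 contiguous blocks with
the full-fit weights held fixed, making it deterministic; in simulation
it runs ~8% below the empirical sd — the familiar behavior of jackknife
SEs for ratio statistics with noisy denominators. No MHC exclusion or
reference-list allele merging: harmonization is the responsibility of
the sumstats layer, and LD scores are inputs (or synthetic), never
estimated from genotypes.

## Synthetic data generator

The generator emulates the structure of a microbiome-exposure MR study
at the summary level: polygenic exposure effects on `n_causal` SNPs with
explained variance summing to `h2_exposure` (default 0.1); outcome
effects θ·βₓ plus per-SNP pleiotropy α on a configurable share of
instruments (directional α is defined relative to the
exposure-increasing allele, so the Egger intercept estimand equals the
configured mean; an InSIDE-violating mode couples α to instrument
strength); an exposure→mediator→outcome chain with true proportion
mediated θ₁θ₂/(θ₁θ₂+θ_direct); block-diagonal LD with exponential r²
decay whose within-block spacing sits inside, and block spacing outside,
the 10,000-kb clump window; and sampling noise with
SE = 1/√(2·eaf·(1−eaf)·N). Default sample sizes mirror the motivating
study design (exposure N = 18,340; binary outcome N = 602,604; mediator
N = 100,000 as a round anthropometric-GWAS scale).

What the generator does **not** emulate: LD-induced correlation between
the *observed* effect estimates of neighboring SNPs (marginal effects
are drawn independently given the truth — adequate because all
estimation happens after clumping to near-independent instruments),
case-control ascertainment (binary-outcome betas are generated directly
on the log-odds scale), sample overlap between the two GWAS, allele
frequency mismatch between cohorts, and indels/multi-allelics. Passing
recovery tests therefore validate the estimators and the pipeline
logic, not robustness to those real-data artifacts.

In mediation chains the mediator inherits θ₁·βₓ at the exposure's causal
SNPs, so very strong exposure instruments can reach genome-wide
significance for the mediator and contaminate the mediator→outcome leg
(their Wald ratio is (θ₁θ₂+θ_direct)/θ₁, not θ₂). The recovery
validation therefore uses a moderate exposure architecture
(h² = 0.05 over 100 instruments at N = 100k), under which contamination
is negligible; with stronger architectures the heterogeneity filter
catches the contaminated leg, which is the designed behavior.

## Problem sizes and numerical choices

Validation simulations use 100–120 instrument-scale SNP panels for
estimator recovery (200 replicates; 1000 for type-I error), a 220-SNP
panel for mediation chains (100 replicates), and M = 5000 SNPs for LDSC
(100 replicates) — sizes at which every Monte-Carlo tolerance in the
test suite is several MC-SEs wide. Empirical p-values use +1 smoothing;
p-values are clipped into (0, 1]; all random draws flow from explicit
`numpy` Generators seeded per replicate, and the orchestration layer
derives per-pair seeds deterministically from the study seed, so a full
`run-all` is byte-identical across reruns. Report TSVs round floats to
4 significant digits; a JSON sidecar preserves full precision.
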