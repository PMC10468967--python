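# Methods

This note records the statistical model behind `mrtriad`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter when reproducing results.

## Two-sample MR model

All estimators consume per-variant summary associations from two
non-overlapping GWAS: exposure effects (β̂_GX, se_GX) and outcome effects
(β̂_GY, se_GY), harmonized to a common effect allele. Outcome effects for
binary traits are log odds ratios. The identifying assumptions are the
usual instrumental-variable ones: instruments are associated with the
exposure, independent of confounders, and affect the outcome only through
the exposure. The diagnostics quantify violations of the third assumption:
Cochran's Q measures heterogeneity of the per-instrument ratio estimates,
and the MR-Egger intercept measures directional pleiotropy under the
InSIDE assumption (instrument strength independent of the direct effects).

- Wald ratio (k = 1): β = β̂_GY/β̂_GX with first-order delta-method SE
  se_GY/|β̂_GX|. A second-order option adds the exposure-uncertainty term
  β̂_GY²·se_GX²/β̂_GX⁴; it matters only for weak instruments and is off by
  default because the first-order form is the field's convention.
- IVW (k ≥ 2): with ratio SEs se_i = se_GY,i/|β̂_GX,i| and weights
  w_i = 1/se_i², β̂ = Σw_iβ_i/Σw_i. Fixed-effect SE (Σw_i)^(−1/2);
  the default multiplicative random-effects model scales it by
  max(1, √(Q/df)) so the SE never drops below the fixed-effect one. The
  default is the conservative choice; the fixed mode is retained because
  oracle tests and the MVMR reduction are exact against it.
- MR-Egger (k ≥ 3): weighted least squares of β̂_GY on β̂_GX with
  intercept, weights 1/se_GY², after flipping pairs so every β̂_GX ≥ 0
  (the intercept is only interpretable relative to the
  exposure-increasing allele). Standard errors come from the WLS fit
  (residual-variance scaled); p-values are two-sided normal, as are all
  other p-values in the package.
- OR-scale reporting uses exp(β) with 95% bounds exp(β ∓ 1.96·se).

### Instrument selection

Screening at four p-value levels (1e-5, 1e-6, 1e-7, 1e-8, strict `<`)
deliberately produces nested candidate sets; results are reported per
level rather than merged. Greedy clumping keeps the smallest-p candidate
and removes neighbours with r² ≥ 0.001 within 10 Mb (standard stringent
defaults; both are configurable since source analyses rarely report
theirs). Ties on p are broken by genomic position for determinism. LD is
supplied as an r² matrix — from the generator or a user file — never
fetched from a reference panel.

### Harmonization policy

The outcome record is aligned to the exposure's effect allele: direct
match, allele swap (sign and EAF flip), strand flip (complement
relabelling), or swapped strand flip; anything else is incompatible.
Palindromic variants (A/T, C/G) cannot be resolved by allele labels, so
they are oriented by which side of 0.5 the two EAFs fall on and dropped
when the exposure EAF lies within w = 0.08 of 0.5 or when either EAF is
missing. These are package policy (common field convention), not an
attempt to reconstruct any particular study's unstated choices.
Harmonizing an already-harmonized pair is a no-op.

## Pipeline decision rules

An exposure-level result is carried into mediation/MVMR when MR p < 0.05
and there is no evidence of heterogeneity or pleiotropy: Q p > 0.05 and
Egger intercept p > 0.05, where a diagnostic that cannot be computed
(k < 2 for Q, k < 3 for Egger) counts as a pass — single-instrument
results legitimately carry "NA" diagnostics. Bonferroni correction
(min(1, p·m)) is applied to single-instrument (cis) results over the
exposure family size m; polygenic results are left unadjusted by default,
with the adjustment scope configurable. The colocalization stage takes the
cis result with the smallest adjusted p and tests its ±50 kb region
against the outcome.

## Mediation

For exposure E, mediator M and outcome O, each edge (E→M, M→O, E→O) is
itself a univariable MR estimate; the proportion mediated is the
product-of-coefficients ratio ρ_M = β_EM·β_MO/β_EO, reported as a percent
to one decimal. Triangles require all three edges at p < 0.05
(unadjusted, configurable). The scan runs both directions for every
cross-pair: pairs significant in both directions are flagged `ambiguous`
and excluded from the mediation summary rather than silently filtered,
because shared instruments genuinely produce bidirectional signal.
Instrument overlap between exposure and mediator is logged, not removed.
ρ_M outside [0, 1] (inconsistent mediation, e.g. sign-discordant paths) is
returned with a warning and marked in the report. No standard error is
attached to ρ_M; it is a point summary of three estimated effects.

## Multivariable MR

Direct effects of m exposures are estimated by WLS of outcome betas on the
m-column exposure-beta matrix without intercept, weights 1/se_GY². The
instrument set is the union of each exposure's clumped instruments,
re-clumped jointly with each variant ranked by its best p across
exposures; union variants missing from any exposure table are dropped and
counted. Exposures are "retained" at p < 0.1 — a deliberately permissive
screen for identifying which mediators matter. Rank-deficient designs
raise a collinearity error naming the most correlated exposure pair. With
m = 1 the estimator reduces exactly to fixed-effect IVW.

## Colocalization

Per-variant evidence is the Wakefield log approximate Bayes factor
log ABF = 0.5·log(V/(V+W)) + z²W/(2(V+W)) with V = se², W = prior_sd²,
z = β/se. Effect-size priors default to prior_sd = 0.2 for quantitative
traits and 0.15 (log-odds) for binary traits. Regional hypothesis sums
under a single causal variant per trait use per-variant priors
p1 = p2 = 1e-4 and p12 = 1e-5 (field-standard defaults; configurable):
H0 = 1, H1 = p1·ΣBF1, H2 = p2·ΣBF2, H3 = p1p2(ΣBF1·ΣBF2 − ΣBF1BF2),
H4 = p12·ΣBF1BF2, normalized to PP.H0–PP.H4. All accumulation is in log
space (log-sum-exp; the H3 difference via log1p) because Bayes factors
overflow double precision in strong regions. Regions are extracted as a
closed ±window interval (default 50 kb) around a lead variant on its
chromosome. No multiple-causal-variant (SuSiE-style) extension is
provided.

## Synthetic-data generator

Summary statistics are simulated directly at the summary level: an
observed beta is its true marginal effect plus N(0, se²) noise with the
analytic SE

    quantitative: se = 1/√(2p(1−p)·n)
    binary:       se = 1/√(2p(1−p)·n·cf·(1−cf))

(p = effect-allele frequency, n = GWAS sample size, cf = case fraction).
This gives correct two-sample sampling distributions at desk scale without
individual-level genotypes.

The default study mimics a microbiome/metabolome-to-disease screen at
roughly 1/100 of its width: 20 quantitative exposures (GWAS n = 18,473;
a metabolite-like mediator default of n = 7,824 is used by the triangle
generator) with 2–26 instruments each, one binary outcome with
n = 1,388,342 and case fraction 5101/1,388,342, five causal exposures at
θ = 0.5 on the log-odds scale, and one planted exposure→exposure chain
(θ_EM = 0.5). Instrument true effects are ±Uniform(0.045, 0.13) — spanning
the four screening levels at the exposure sample size — with EAFs
Uniform(0.05, 0.95). Each instrument comes with two satellite variants in
an AR(1) LD block (ρ = 0.9) so clumping has real work; 50 independent null
variants pad the panel; the outcome table's allele orientation is randomly
swapped/strand-flipped per variant so harmonization has real work.
Pleiotropic outcome effects are planted relative to the
exposure-increasing allele: balanced ~ N(0, mag²), directional
~ N(mag, (mag/2)²). The directional spread (mag/2) keeps the InSIDE-style
variation that the Egger intercept SE is estimated from. Colocalization
regions use the z-score model: z ~ N(√n·R·b, R) over an AR(1) r matrix
(ρ = 0.9, 200 variants, n = 50,000 per trait, causal standardized effect
0.05), with distinct-variant scenarios placing the second causal variant
60 positions away (effectively unlinked).

Everything is reproducible bit-for-bit from (config, seed).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sample overlap between the two GWAS,
population stratification and relatedness, winner's-curse from discovery =
selection cohorts, LD beyond block-AR(1), allele-frequency mismatch
between cohorts, INDELs/multi-allelics, and any real biology of taxa or
metabolites. Calibration results here validate the estimators and decision
rules under their own assumptions, not robustness to those violations.

## Simulation study sizes

Calibration checks use sizes chosen to give stable Monte-Carlo estimates
while keeping the default test run quick: 1000 replicates for type-I error
and Egger null calibration, 200 seeds for coverage and Egger power, 20–40
seeds for mediation recovery and colocalization discrimination, and 20
pipeline runs for planted-exposure recovery. The mediation recovery
configuration (k = 200/100 instruments, outcome n = 1e6 with case fraction
0.3, instrument effects 0.13–0.18 with EAF 0.3–0.7, θ_EM = 0.08) was
derived from a power analysis with two constraints: edge estimates precise
enough to resolve ρ_M to ±0.05, and inherited exposure signals on the
mediator kept far enough below the screening threshold that the mediator's
instrument set is not contaminated (contamination would make the reverse
edge genuinely significant and bias β_MO).

## Known limitations

- No weighted-median/mode estimators, MR-PRESSO, Steiger filtering or
  conditional F-statistics; the diagnostics are Q and the Egger intercept
  only.
- ρ_M carries no interval; two-step MR delta-method CIs are out of scope.
- The Egger intercept SE uses the standard residual-scaled WLS form; with
  few instruments its null p-values are mildly conservative/anticonservative
  relative to an exact t reference (the calibration test uses k = 20 where
  the normal approximation is adequate).
- Single-causal-variant colocalization only; no eQTL lookup or regional
  plotting.
- LD must be supplied; there is no computation of LD from genotypes and no
  proxy-variant search.
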