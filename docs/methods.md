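# Methods

## Design and estimands

The analysis concerns a retrospective case–control design with two binary
carrier exposures. Subjects are classified HLA-B27 positive when their
rs13202464 genotype is GG or AG and negative when AA (the SNP tags B27
with reported sensitivity 98.7% / specificity 98.0%; these constants are
carried as metadata and never recomputed). HLA-B60 carriership is taken
directly from its assay. Cross-classification yields a 2×2×2 table with
stratum order (B27⁺/B60⁺, B27⁺/B60⁻, B27⁻/B60⁺, B27⁻/B60⁻), reference
last; subjects missing either factor are excluded listwise with a logged
count.

All effect measures are odds ratios used as relative-risk surrogates
under the rare-disease assumption (AS prevalence 0.167%). Stratum ORs
are cross-products against the reference with Wald intervals
exp(log OR ± z·se), se = √(1/a + 1/b + 1/c + 1/d), z the exact 0.975
normal quantile (≈1.959964). Fisher's exact p is two-sided by the
point-probability convention (sum of hypergeometric probabilities not
exceeding the observed one, with a 1+1e−7 relative guard for floating
ties), matching mainstream software; the summation is ours, the
hypergeometric pmf is scipy's.

## Logistic fitting

Grouped binomial-logit models over the four covariate patterns are
fitted by Newton/IRLS from β = 0, without regularisation; convergence
requires max |Δβ| < 1e−10 or relative log-likelihood change < 1e−12
within 50 iterations. The covariance is the inverse observed information
(equal to expected information for the canonical link). Grouped fitting
gives the identical MLE to subject-level rows with far better
conditioning. The saturated model's fitted stratum probabilities equal
the empirical proportions, so exp(β₁) = OR₁₀, exp(β₂) = OR₀₁,
exp(β₁+β₂+β₃) = OR₁₁ exactly; its coefficient covariance also has a
closed form in reciprocal cells (var(log OR) per stratum plus the shared
reference term 1/a₀₀ + 1/b₀₀ off-diagonal), used as an independent
cross-check at 1e−6 relative tolerance. Empty strata or one-armed strata
under the saturated model raise a separation error naming the stratum.

## Interaction measures

RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1, AP = RERI/OR₁₁ and
S = (OR₁₁−1)/((OR₁₀−1)+(OR₀₁−1)) are computed from the saturated fit.
Delta-method variances are gᵀVg with V the covariance of
(log OR₁₁, log OR₁₀, log OR₀₁) and gradients (OR₁₁, −OR₁₀, −OR₀₁) for
RERI, ((OR₁₀+OR₀₁−1)/OR₁₁, −OR₁₀/OR₁₁, −OR₀₁/OR₁₁) for AP, and
(OR₁₁/(OR₁₁−1), −OR₁₀/D, −OR₀₁/D) with D = (OR₁₀−1)+(OR₀₁−1) for log S.
RERI/AP intervals are natural-scale symmetric; S is interval-transformed
on the log scale — both conventions confirmed by the log-symmetry of the
published S interval. S is an error when D ≤ 0; OR₁₁ ≤ 1 is flagged with
a warning (and a negative S gets no log-scale interval). The bootstrap
alternative resamples the case and control arms as independent
multinomials over the four strata (the sampling actually performed in a
retrospective design), excludes replicates with undefined measures (error
above 10%), and reports percentile intervals; it is seeded and
reproducible.

## Reconstruction of the published table

Given arm totals and per-factor carrier counts, only two cells are free:
x = cases(B27⁺,B60⁺) ∈ [max(0, 431+100−471), min(431,100)] = [60,100] and
y = controls(B27⁺,B60⁺) ∈ [0,43]. All 41×44 = 1804 candidates are
enumerated and matched against printed statistics at the printed
rounding (coefficients to 4 decimals; large ORs to integers, the small
one to one decimal).

A structural fact drives the design: the grouped main-effects likelihood
depends on (x, y) only through x + y — its sufficient statistics are the
fixed marginals plus the stratum totals — so matching the published
coefficient table alone identifies the ridge x + y = 95 (36 candidates),
never a single table; the same holds for the coefficient SEs. The
printed stratum ORs, by contrast, identify the table uniquely. The
canonical reconstruction therefore matches ORs (or the combined
six-statistic criterion) and cross-validates: the OR-unique table lies
on the coefficient ridge and reproduces the printed coefficient table
*and* its SEs to all four decimals. Exhaustive search rather than
algebra: at ≤ ~2000 candidates it is trivially correct and runs in
seconds.

## Power

One-stage power follows the two-proportion normal approximation for the
carrier (dominant) test: expected case-arm carrier frequency
p₁ = OR·p₀/(1 + p₀(OR−1)), critical value from the null-pooled variance,
noncentrality from the alternative variances, two-sided at α, clipped to
[0,1]. At the study's sizes it saturates (1.000 at three decimals) for
any carrier OR above ~10, reproducing the published B27 claim; for the
B60 effect (OR ≈ 1.79) it gives ≈0.93, so the published "1.000 for both"
is not reproducible from the printed inputs and is reported as computed.

## Severity

Kruskal–Wallis on midranks with tie correction
1 − Σ(t³−t)/(N³−N) and chi-squared p (df = k−1); the uncorrected H is
also reported since the source does not state whether ties were
corrected, and a seeded Monte-Carlo permutation p is available for small
samples. Group summaries use the n−1 sd. The published per-stratum
means ± SDs and group sizes (88, 334, 12, 25; total 459 of 471 cases —
the missingness mechanism is unstated and not modelled beyond an
optional missing-at-random mask) parameterise the synthetic severity
fixture; the published exact p-values depend on unpublished individual
scores and are out of reach by construction.

## Synthetic-data generator

Controls draw stratum membership from the specified joint carrier
frequencies (defaults: the reconstructed control distribution
(7, 36, 66, 448)/557); case strata use the same frequencies weighted by
the stratum ORs (reference weight 1) and renormalised, which makes the
expected stratified ORs equal the generating ones. Carriers emit GG or
AG with equal probability (the analysis uses carriership only; the split
is an arbitrary documented choice), non-carriers AA. Prevalence (0.00167)
is carried for documentation and the power linkage only — retrospective
sampling never uses it.

Severity scores are truncated-normal on [0,10]. Truncating a normal that
*has* the target moments would bias the realised mean upward by ~0.7
where the mean sits ~1 sd from a bound, so the generator solves for
parent (loc, scale) whose truncated mean equals the target exactly and
whose truncated sd is as close as feasible — a [0,10]-truncated normal
cannot exceed a coefficient of variation of ~1 near a bound, so BASFI
strata with sd > mean (e.g. 2.02 ± 2.19) receive the feasibility cap
(realised sd ≈ 1.88). Real instrument scores are zero-inflated and
skewed in ways this family does not capture; passing tests show the
pipeline handles data with the published first two moments, not that the
distributional shape is realistic.

What passing tests show more generally: estimation is calibrated under
the generator's own design (multinomial arms, independent strata,
no covariates, no genotyping error); they do not speak to population
stratification, tag-SNP misclassification, or covariate confounding,
none of which the source analysis modelled either.

## Numerical and testing choices

Monte-Carlo problem sizes were chosen to keep every check comfortably
inside a desk-scale run: 600 replicates for the two RERI coverage
experiments (study-scale target 90–98%, additive-null target 93–97%),
200 replicates at 10× scale for log-OR consistency (allowing the
analytic first-order bias 0.5·Σ1/μ of the cross-product estimator on top
of 2 Monte-Carlo SEs), 10,000 bootstrap replicates on the study table,
and exhaustive Fisher agreement with scipy for every 2×2 table of total
≤ 22 plus 200 random larger tables against an exact-rational enumeration
oracle. The severity fixture (seed 20150, frozen) is checked against the
published moments by an aggregate chi-squared bound at the 99.9% level —
the correctly calibrated joint form of a per-stratum 2-SE check, which
would fail for ~40% of seeds purely by construction.

## Known limitations and flagged discrepancies

- The published marginal B27 OR (120.80) is inconsistent with its own
  printed counts (431·514/(40·43) = 128.80); the computed value is
  reported and the printed one treated as a typo.
- The published Fisher p-values for the two single-exposure strata
  appear swapped (recomputed: 1.2×10⁻¹⁵⁷ for OR 152, 0.0072 for OR 2.9);
  both are recomputed and neither pairing matched.
- The published lower bound of the marginal B60 CI (1.29) equals the
  Wald bound around the *rounded* point estimate; the bound of the
  counts themselves is 1.2840.
- Only two-factor, two-arm designs are supported; no covariate
  adjustment, no Mantel–Haenszel pooling, no multiplicative-scale
  interaction test beyond the descriptive sum/product comparison.
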