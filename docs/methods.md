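# Methods note

This note records the statistical model implemented by `snpmeta`, the
assumptions behind it, the parameters and their defaults, the numerical
choices that affect results, and known limitations.

## Data model

The unit of analysis is a case-control study of a biallelic SNP with risk
allele A and reference allele G. A study record carries, per arm (case,
control), either the genotype triple (n_AA, n_AG, n_GG) or only the
risk-allele frequency (RAF) and arm size. Studies may additionally carry
case strata (ER+/ER−, PR+/PR−) that share the parent study's control arm.
Ethnicity labels are mapped to four analysis groups (White, EastAsian,
African, Other) through a shipped lookup table; multi-ethnic labels use the
first listed ethnicity, and unmapped labels fall back to Other with a
warning. Input validation is strict: genotype triples must sum to the arm
size, RAFs must lie in [0, 1], and when both a genotype triple and a RAF
are present for the same arm they must agree within 0.005 (allowing for
two-decimal rounding in published tables).

When only RAF and arm size are available, the allele-contrast 2×2 table is
reconstructed as a = round(2·N·RAF) risk alleles out of 2N, with
half-away-from-zero rounding so that a + b = 2N exactly. Genotype-based
contrasts (dominant, recessive, heterozygous, homozygous) are only
available for studies with genotype triples; requesting one on a
frequency-only study raises a capability error naming the usable models,
and the pipeline records the skip and continues rather than aborting.

## Per-study effects

All five contrasts reduce to a 2×2 table analyzed by the Woolf estimator:
log OR = ln(ad/bc) with variance 1/a + 1/b + 1/c + 1/d. If any cell is
zero, 0.5 is added to all four cells (Haldane–Anscombe); if an entire
margin is zero (a = c = 0 or b = d = 0) the effect is non-estimable and an
error is raised. Confidence intervals use z = 1.959964.

## Pooling

* Inverse-variance fixed effect: weights 1/vᵢ on the log scale.
* DerSimonian–Laird random effects: τ² = max(0, (Q − (k−1)) / (S₁ −
  S₂/S₁)) with S_r = Σwᵢʳ, then weights 1/(vᵢ + τ²). Truncation at zero is
  the standard moment-estimator convention; it means τ² = 0 is reported
  whenever Q ≤ k − 1.
* Mantel–Haenszel fixed effect: OR = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ) with the
  Robins–Breslow–Greenland variance for the log OR; the accompanying Q
  statistic is computed on the Woolf effects.

Heterogeneity is Cochran's Q (χ², k−1 df) and I² = max(0, (Q − df)/Q).
The pipeline's headline estimate is the per-allele DerSimonian–Laird
result; with substantial I² a random-effects summary is the defensible
default, and it coincides with the fixed-effect one when τ² = 0.

## Moderator analyses

Subgroup analysis partitions fixed-effect Q exactly: Q_total = ΣQ_within +
Q_between, where Q_between is computed from inverse-variance group means
and weights. This identity holds only for fixed-effect weights, so
Q_between always uses them even when the reported subgroup summaries are
random-effects. Subtype contrasts (e.g. ER+ vs ER−) pool each stratum
across studies and compare them with an independent-strata z-test; because
both strata share each study's controls the estimates are positively
correlated, so the test is mildly conservative for the difference (the
shared-control covariance is not subtracted). Meta-regression uses
method-of-moments τ²: τ² = max(0, (Q_E − (k − p)) / (tr(W) −
tr((XᵀWX)⁻¹XᵀW²X))), followed by weighted least squares with normal-theory
z-tests on coefficients. Rank-deficient design matrices raise an error
naming the collinear columns; k ≤ p raises an insufficient-studies error.
With an intercept-only design the result equals DerSimonian–Laird exactly.

## Hardy–Weinberg screening

Control genotype triples are tested by Pearson χ² with 1 df against
expected counts from the estimated allele frequency. Studies failing at
α = 0.05 (default) are excluded before pooling and written to the bundle's
exclusion table. Frequency-only studies cannot be tested and are retained
with a `not_testable` flag rather than silently treated as passing.

## Publication bias and sensitivity

* Egger: regress yᵢ/seᵢ on 1/seᵢ; the intercept's t-test (k − 2 df) is the
  small-study-effect test. A degenerate-fit guard handles exact fits
  (residual sum of squares ≤ 1e−12 relative to max(1, max yᵢ²)): the
  machine-noise t statistic is replaced by t = 0, p = 1 when the intercept
  is itself negligible, rather than reporting an arbitrary p-value.
* Begg–Mazumdar: Kendall correlation between standardized deviates
  (yᵢ − ȳ_fixed)/sqrt(vᵢ − v_pooled) and vᵢ, with S counted by brute
  force over all pairs, tau-a denominator k(k−1)/2, tie-corrected variance
  of S and the |S| − 1 continuity correction; variance terms are clamped at
  1e−12 so near-zero variances cannot produce NaNs, and S = 0 reports
  p = 1. Begg's test has low power at k ≈ 26; a non-significant result is
  weak evidence of absence.
* Influence: leave-one-out re-pooling under the chosen method, reporting
  the range of pooled ORs and whether any omission makes the CI cross 1.

## Synthetic-study generator

The generator draws study collections from the assumed data-generating
process, so estimators can be validated by parameter recovery:

1. Per study, an ethnic group is drawn from a fixed mix and a control RAF
   p₀ from a Beta distribution for that group.
2. Control genotypes are multinomial with HWE probabilities
   (p₀², 2p₀(1−p₀), (1−p₀)²).
3. A per-study per-allele odds ratio λᵢ = exp(N(ln OR_true, τ²)) induces
   case genotype probabilities proportional to (λᵢ², λᵢ, 1) × HWE, so the
   heterozygote-vs-GG odds ratio is exactly λᵢ and the homozygote one λᵢ².
   The implied case RAF has the closed form p₁ = λp₀/(λp₀ + 1 − p₀).
4. Optional ER/PR case strata are drawn with subtype-specific odds ratios;
   strata within a study share its heterogeneity deviate (λ_sub =
   OR_sub · λᵢ / OR_true), so between-study and between-subtype variation
   are not confounded.

Dominant and recessive modes of action replace the (λ², λ, 1) weights with
(λ, λ, 1) and (λ, 1, 1) respectively.

Defaults are chosen to resemble a multi-ethnic breast-cancer SNP
meta-analysis: k = 26 studies mixed 14/6/5/1 over
White/EastAsian/African/Other; Beta control-RAF means 0.51, 0.12, 0.72,
0.55 with concentrations 100, 40, 30, 30 (tighter for the well-sampled
White group); true per-allele OR 1.14; τ² = 0.002; arm sizes log-uniform
on (500, 10000); GWAS design fraction 5/26; subtype odds ratios 1.17/1.08
(ER) and 1.18/1.10 (PR) with ER+ prevalence 0.70 and PR+ 0.65. The
generator emulates sampling variation, allele-frequency structure across
ancestries, between-study heterogeneity and subtype structure. It does not
emulate genotyping error, control-source (population vs hospital)
confounding, selective publication, linkage disequilibrium with a causal
variant, or covariate-adjusted effect estimates — simulated and real
moderator effects for control source are therefore null by construction.

## Numerical and testing choices

* Half-away-from-zero rounding for allele reconstruction (Python's
  `round` is banker's rounding, which would bias reconstructed counts at
  .5 boundaries).
* z = 1.959964 for 95% intervals throughout.
* τ² truncated at 0 (moment estimators can go negative).
* Egger calibration is checked under τ² = 0: Egger's null is "no
  small-study effect", and heterogeneity is a known confounder of the test
  rather than part of its null.
* Recovery and calibration tests use fixed seeds with replicate counts
  (100–5000) and tolerances (±0.02–0.03 on log OR, ±0.01–0.02 on rejection
  rates, coverage within [0.92, 0.975]) sized so that Monte-Carlo error is
  a small fraction of the tolerance.

## Limitations

* Frequency-only reconstruction recovers allele 2×2 tables, not genotype
  tables, so genotype-model contrasts are unavailable for such studies and
  HWE cannot be tested on them.
* Under heterogeneity, random-effects pooling down-weights large studies
  relative to fixed-effect pooling; on the shipped example table the
  DerSimonian–Laird and fixed-effect summaries differ at the second
  decimal (the pipeline reports both on request via `--method`).
* The subtype z-test ignores the shared-control covariance (conservative).
* DerSimonian–Laird understates uncertainty in τ² itself; no
  Hartung–Knapp or profile-likelihood adjustment is implemented.
* Begg's and Egger's tests have low power at typical k; funnel-plot data
  are exported for visual assessment but plotting is out of scope.
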