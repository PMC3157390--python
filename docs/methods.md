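# Methods

## The replication-expectation model

A replication panel is a list of published SNP–trait associations, each
with a risk allele, a risk-allele frequency (RAF), a published per-allele
odds ratio (binary traits) or regression coefficient (quantitative
traits), and the cohort's case/control counts after phenotyping. Each
association is tested once, one-sided in the published direction, at
α = 0.05. Whether the panel "replicated well" is judged not against the
raw count but against the distribution of the count implied by per-
association power: replication attempt *i* is an independent
Bernoulli(pᵢ) trial with pᵢ equal to its analytic power, so the number of
successes follows a Poisson-binomial distribution. We compute that
distribution exactly and ask whether the observed count falls inside its
95% prediction interval.

## Power model for the trend test

Power is computed only for binary traits, under the classical case-control
framework for the Cochran–Armitage trend test:

- **Genotypes.** Population genotype frequencies are Hardy–Weinberg at the
  published RAF q: ((1−q)², 2q(1−q), q²).
- **Penetrance.** Disease odds are logit-additive in the allele count,
  odds(g) = odds₀·ORᵍ. The baseline odds₀ is solved numerically (Brent's
  method on the log scale) so the population prevalence matches the
  configured value. Case and control genotype distributions follow by
  Bayes' rule. The per-allele OR is the only effect-size input the
  catalogs report, which is why the multiplicative-odds genetic model is
  used rather than dominant/recessive alternatives.
- **Misclassification.** With case error e₁ and control error e₂, the
  *observed* case genotype distribution is (1−e₁)·case + e₁·control and
  symmetrically for controls. This is the mixture interpretation — e₁ is
  the fraction of reported cases that are truly controls — and it
  attenuates the mean-dosage contrast, which is how phenotyping error
  costs power. Defaults: e₁ = 0.05 (misdiagnosis rates for most diseases
  exceed 5%) and e₂ = min(prevalence, 0.10) (a reported control is a
  latent case with probability bounded by prevalence, capped because the
  control age rule below truncates residual risk at 10%).
- **Proxy dilution.** When a proxy SNP with squared correlation r² to the
  reported SNP is tested, both group sizes are multiplied by r²
  (effective sample size n·r²); non-integer effective sizes are used
  as-is.
- **Normal approximation.** With R effective cases and S effective
  controls, observed-group dosage means μ₁, μ₀ and variances v₁, v₀, and
  the size-weighted pooled distribution's variance v_p, the one-sided
  power at level α is
  Φ((|μ₁−μ₀| − z_α·√(v_p(1/R+1/S))) / √(v₁/R+v₀/S)).
  For a two-sided α both rejection tails are summed (so null power equals
  α under either sidedness). The variance uses the genotype scores 0/1/2
  — the same statistic the cohort-side trend test computes — rather than
  the allele-count (2R alleles) variance; under HWE the two coincide
  asymptotically, but the genotype-score form is exactly the test being
  run, and it reproduces the package's three worked-example powers
  (77/95/77%) at the default prevalence. No continuity or small-sample
  correction is applied.
- **Worked-example prevalence.** The three worked examples (README) fix
  RAF 0.30, OR 1.3 and a two-sided 10⁻⁷ threshold but do not pin a
  prevalence; the package uses 1% — a representative complex-disease
  value in the rare-disease regime where the result is insensitive to the
  choice (the rounded powers are unchanged for any prevalence ≤ 1% and
  drift by at most one point up to 5%).

**Winner's curse.** Discovery studies overestimate effect sizes. The
adjustment is multiplicative on the log-OR: inflate maps log OR ↦
log OR·(1+κ), deflate inverts it; κ = 0.15 is the reference scenario
(OR 1.25 ↦ 1.3, 1.41 ↦ 1.5). Deflation is applied to the published OR
before the power calculation when enabled; it is off by default.

## Exact count distribution and prediction interval

The Poisson-binomial pmf is computed by the dynamic-programming recurrence
fᵢ(k) = fᵢ₋₁(k)(1−pᵢ) + fᵢ₋₁(k−1)pᵢ from a point mass at zero — O(n²)
and exact to floating-point accuracy (verified against exhaustive 2ⁿ
enumeration to 10⁻¹² for n ≤ 15). The 95% prediction interval takes the
largest L with P(X < L) ≤ 2.5% and the smallest U with P(X > U) ≤ 2.5%,
both with weak inequalities, so coverage is always ≥ 95% (discreteness
makes it typically 95–96.5%). Ratio intervals divide the integer bounds
L, U by the expected count Σpᵢ, not by the number of attempts.
Associations untestable in the cohort (monomorphic genotype, empty group)
are removed from both the observed and the expected side before
summarising. The directionality expectation recomputes each power at a
one-sided α of 0.5 — the probability that the estimate merely lands on
the published side of zero — restricted to the non-replicated
associations.

## Curation and phenotyping rules

Numerical/tie-break choices where the rules alone do not force one:

- Deduplication keeps the study with the most cases; ties break to
  smaller p, then lexicographic study id (determinism).
- LD blocks are connected components of the r² ≥ 0.1 graph; pairwise-only
  pruning would be order-dependent. Missing LD pairs are treated as
  r² = 0, which conservatively keeps both associations. Pruning is per
  phenotype, since associations are phenotype-specific.
- Proxy choice takes the highest-r² candidate that is itself well-called
  on the platform (ties: smallest rsID).
- The strand frequency band is strict: a reported and reference frequency
  match only if both are < 0.35 or both are > 0.65. Ambiguous (A/T, C/G)
  pairs and SNPs without reference frequencies go to a manual-review list
  rather than being resolved automatically; entries marked unresolvable
  by the analyst are excluded from testing.
- "Inconsistent" answers are judged within one phenotype's question set
  only. Incidence curves are piecewise-linear between tabulated ages; a
  control's residual lifetime risk is (F∞−F(a))/(1−F(a)), and the age
  restriction is skipped entirely when F∞ ≤ 10%. Attained age at survey
  is used.
- The association tests themselves carry no covariates; covariates enter
  only the risk-report interaction regression. Missing genotypes are
  dropped per association (complete case). One-sided p-values come from
  the signed normal score statistic. Separated logistic fits are flagged
  with an infinite-width interval rather than penalised.

## Synthetic data: what it emulates and what it does not

The generator draws HWE genotypes, applies the same penetrance model the
power calculation assumes, flips true case labels to reported controls
with probability e₁ and true controls to reported cases with e₂, builds
proxy SNPs from two-locus haplotype frequencies with D solved from the
target r² (positive phase; infeasible targets raise with the feasible
range), and emits two-question surveys with configured fractions of
uncertain-only and inconsistent responders (defaults 5% and 1% — plausible
magnitudes for online questionnaires). Catalog fixtures are
self-labelling: every row carries the curation outcome it is engineered to
trigger. Defaults emulate a cohort of 20,000 mostly unselected subjects
and a panel of modest effects (OR 1.1–1.5, RAF 0.1–0.5, prevalence
1–20%).

Passing tests on these data show that the pipeline is internally
consistent — that analytic power matches the rejection rate of the actual
test on data drawn from the assumed model, and that prediction intervals
cover at their nominal rate *when the model is true*. They cannot show
that real self-report error is symmetric, independent of genotype, or of
the assumed magnitude, that published ORs are unbiased (they are not —
hence the winner's-curse knob), or that real LD structure reduces to
pairwise r². Cohort ascertainment, population structure beyond synthetic
PC covariates, and haplotype-level association are not modelled.

## Problem sizes in the test suite

Monte-Carlo checks use vectorised multinomial genotype-count sampling:
10,000 replicates per point on an 18-point power-calibration grid
(group sizes 200/1000 × OR 1.0/1.3/1.5 × error 0/5/15%), 1,000 full
pipeline replicates of a 200-association panel for end-to-end interval
coverage, and 10,000 null replicates at 2,000 cases/2,000 controls for
the KS uniformity check; the whole suite runs in well under a minute.
Calibration tolerances are two binomial standard errors of the replicate
count (with a small floor where the analytic value sits near 0 or 1).

## Known limitations

- Power for quantitative traits is not computed (published effect scales
  are rarely commensurable across instruments); quantitative associations
  still get tests and replication calls.
- The normal-approximation power carries O(1/n) bias (measured ≈ 0.002 at
  200 cases/controls and mid-range power), negligible for expectation
  accounting but visible in very small groups.
- The Poisson-binomial model assumes independent replication attempts;
  residual LD between curated SNPs (r² < 0.1) and shared subjects across
  phenotypes induce small positive dependence that the prediction
  interval ignores.
- Strand review is a human step by design; the package only triages.
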