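# Methods

## Estimand and model

For sibs i, j of the same family, the full-sib regression slope β_FS is the
slope of sib i's phenotype regressed on sib j's.  Under the classical
polygenic model β_FS = (0.5 V_A + 0.25 V_D + V_Ec) / V_P, where V_A, V_D,
V_Ec and V_P are the additive genetic, dominance, common-environment and
total phenotypic variances.  The Falconer conversion h² = 2 β_FS (with SE
doubled) is therefore an upper-bound-style heritability estimate that is
exact only when V_D, V_Ec and assortative mating are negligible; every
`FalconerResult` carries this assumption statement explicitly.

The package's central object is the *quantile slope function* β_FS(τ): for
each percentile τ, the coefficients (a(τ), β_FS(τ)) minimise the check
(pinball) loss Σ ρ_τ(y − a − b·x), ρ_τ(u) = u(τ/100 − 1{u<0}), over the
double-entered pair set.  A flat function reproduces the classical analysis;
a rising function means the familial effect size grows with the phenotype
level (quantile-dependent expressivity).

## Pair construction and degrees of freedom

All ordered within-family pairs (i, j), i ≠ j, are materialized ("double
entry"), which symmetrizes the dependent and independent margins and makes
the OLS slope equal the Pearson correlation of the pair set.  Because each
unordered pair enters twice, inference never uses n_pairs − 2 df: all t
references use Σ(kᵢ − 1) over families, kᵢ being the number of sibs usable
in the analysis at hand.  Sibs with a missing value for the analysed
phenotype drop out listwise for that phenotype only.  For sibships of size
k > 2 the default pairs each sib against every co-sib separately; a
`co_sib_mean` switch pairs each sib once against the mean of its co-sibs for
users who prefer that reading.  Sex-restricted analyses filter the
*dependent* sib's sex only; the co-sib may be of either sex.

Age/sex adjustment regresses the phenotype on (1, female, age, age²,
female·age, female·age²) and returns residual + grand mean, preserving
units and the raw mean so percentile grids remain concentration-
interpretable.  Rank-deficient designs (e.g. single-sex data) drop collinear
columns deterministically left-to-right and record what was dropped; a
pseudo-inverse would silently split coefficients across aliased columns and
harm auditability.  The "unadjusted" mode regresses the *raw* dependent sib
value on adjusted co-sib values, matching the pooled single-curve display.
Adjustment is always fitted on the full retained sample, noted in the model
audit record.

## Quantile-regression solvers

Each τ-fit is a 2-parameter LP.  Two solvers are provided:

* **exact** — the split-residual formulation min τ·1'u⁺ + (1−τ)·1'u⁻ s.t.
  a + b·x + u⁺ − u⁻ = y, solved sparsely with HiGHS.  Its optimum is a basic
  solution interpolating ≥ 2 data points; tests verify the attained loss
  equals an exhaustive basis-pair enumeration to 1e-9.
* **irls** — iteratively reweighted least squares with weights
  w = (τ or 1−τ)/max(|r|, 1e-6), the inner loop compiled with numba and
  vectorised over all (replicate, τ) combinations via multinomial row
  weights.  On continuous data it agrees with the LP to ~1e-6 on the slope
  (asserted in tests at 5e-4) at a small fraction of the cost; it exists
  because grid-by-replicate refitting makes exact LPs impractical at
  bootstrap scale.

`fit_quantile` defaults to exact; `fit_grid(method="auto")` uses the LP when
n_pairs × n_grid ≤ 30 000 and IRLS above; `bootstrap_vcv` defaults to IRLS
throughout.  Fitted conditional quantiles at the median predictor are
checked for τ-crossings, which are counted and logged, never fatal (crossing
is a known finite-sample property of per-τ fits).

## Bootstrap inference

Point estimates are per-τ fits on the full pair set; "simultaneous"
inference comes from refitting the *entire grid* on each bootstrap resample,
so the sample covariance of the replicate slope vectors estimates the joint
variance–covariance matrix Σ̂ across percentiles.  The default resampling
unit is the **sibship**: double-entered pairs are strongly dependent within
family, and resampling families preserves that dependence (row resampling
via `unit="pair"` is provided for comparison and demonstrably understates
SEs on clustered data — a test asserts the ordering).  Per-replicate streams
are seeded as (master seed, replicate index, redraw attempt), so enlarging
n_boot extends the replicate set without reshuffling earlier replicates;
degenerate resamples are redrawn at most 10 times.  n_boot ≥ 50 is enforced;
1000 is the recommended reporting default.

Trend tests use unit-norm discrete Gram polynomial contrasts c_d built by QR
on a centered/scaled Vandermonde basis over the (equally spaced) grid —
numerically stable at 91 points and proportional to the classical
equally-spaced contrast tables.  The degree-d statistic is
t = c_d'β̂ / √(c_d'Σ̂c_d) on Σ(kᵢ−1) df; each degree is a single-degree
contrast, not a sequential model comparison.  The linear trend is also
re-expressed as a per-percentile rate via the least-squares line through
(τ, β̂(τ)) — the same t statistic on an interpretable scale.  Pairwise
contrasts β̂(τ_hi) − β̂(τ_lo) use SE² = Σ̂[hi,hi] + Σ̂[lo,lo] − 2Σ̂[hi,lo];
fold-ratio uncertainty is reported as the 95% percentile interval of the
replicate ratios, because the delta method is unreliable near small
denominators.

## P–P sex matching

Comparing sex-specific slope functions at equal percentiles of their
separate distributions compares them at different concentrations whenever
one distribution is shifted.  The P–P construction maps each percentile p of
the pooled distribution to the concentration Q_combined(p) and then to the
percentiles p_female, p_male at which each sex reaches that concentration;
each sex's slope function is evaluated (linear interpolation in τ) at its
own mapped percentile.  ECDF convention: midpoint plotting positions
(i − 0.5)/n with linear interpolation between order statistics, used for
both the quantile function and its inverse so Q(F(v)) ≈ v within the data
range.  Mapped percentiles outside the fitted 5–95 grid are flagged
undefined, never extrapolated.  The pooled distribution is the pooled
individual values, not an average of sex quantiles.

## G×E interaction algebra

A 2 × G means table ties its two difference readings by
dC(g₁) − dC(g₂) = dG(c₁) − dG(c₂).  `pivot_interaction` recovers the
unpublished genotype difference from three published numbers;
`consistency_check` evaluates the identity residual as a transcription
guard, warning above 0.15 ng/ml (published values are rounded to 1 d.p., so
|residual| up to ~0.15 is expected rounding noise).  SEs are echoed only
when the source printed them — the pivoted difference's SE is *not*
synthesised from the other three SEs, whose covariance in the source study
is unknown.  Tables in the shipped corpus that do not determine both sides
of the identity are marked `status: partial` and refuse the consistency
check rather than guessing missing cells.  The line-graph series plots
dG(c) against the condition's mean level (published pooled mean when
printed, else the unweighted mean of genotype cell means).

## Synthetic cohorts and calibration

The generator draws family sizes i.i.d. from {2: 0.45, 3: 0.40, 4: 0.12,
5: 0.03} (mean ≈ 2.7 sibs/sibship; singletons allowed to exercise df
bookkeeping), ages truncated-normal (mean 40, SD 8.7, minimum 16), sexes
Bernoulli(0.5), and latent values z = μ + δ·female + g₁·age + g₂·age² + fᵢ +
e with Var(f) = ρσ², Var(e) = (1−ρ)σ², so the within-family latent
correlation is exactly ρ.  Quantile dependence is induced by a monotone
convex transform of this homoscedastic latent model rather than an explicit
level-dependent loading: that choice yields exact closed-form nulls —
identity sibs are bivariate normal, whose conditional τ-quantile is the line
ρ·x + c(τ), i.e. a flat slope function at ρ for every τ (`analytic_flat_slope`),
and log of a location-0 lognormal cohort recovers the latent model exactly —
plus a guaranteed-monotone alternative.  An explicit level-dependent-loading
generator is included for robustness checks only.

`SyntheticConfig.paper_like()` is calibrated once, in closed form, to the
emulated cohort: matching the male lognormal mean 8.08 ng/ml and CV
6.04/8.08 gives σ² = log(1 + CV²) ≈ 0.444 and scale = 8.08/exp(σ²/2) ≈ 6.47;
the female/male mean ratio fixes δ = log(17.95/8.08) ≈ 0.80.  A single σ
cannot match both sexes' CVs (the female SD comes out ≈ 13.4 vs the
emulated 16.96); the calibration targets the printed means, which the
generated cohorts reproduce well within sampling noise.  Mild age effects
(g₁ = 0.008, g₂ = −5·10⁻⁵ latent units) are absorbed into μ so they do not
move the marginal means.

What the generator does *not* emulate: heavier-than-lognormal tails,
age-dependent variance, assortative mating, parent generations, genotype
effects, or sex-specific latent correlations.  Passing tests therefore show
the pipeline recovers known structure of this family of data-generating
processes — not that real cohort data satisfies the model.

## Test problem sizes

Monte-Carlo checks use a 19-point equally spaced grid (5, 10, …, 95) and 50
bootstrap replicates per cohort for replication studies — the coarse grid is
equally spaced, so trend contrasts are exact on it, and slope functions are
smooth enough in τ that nothing is lost for calibration purposes — while
single-cohort demonstrations use the full 91-point grid with 200 replicates.
Flat-null calibration runs 100 cohorts of 1500 two-sib families (ρ = 0.3);
alternative-detection runs 100 skewed cohorts of 1100 sibships; sex-matching
runs 25 replicates with female-dependent, male-dependent and pooled fits.

## Known limitations

* β_FS conflates V_A, V_D and V_Ec; the package reports the estimand
  explicitly but cannot separate the components.
* Per-τ fits may cross; crossings are diagnosed, not repaired (no smoothing
  or rearrangement across τ, matching the raw per-τ reporting convention).
* The IRLS path is an ε-smoothed approximation; in the rare degenerate
  geometry where the LP optimum is non-unique the two solvers may pick
  different vertices of the same optimal face (identical loss).
* The sibship bootstrap treats families as the only dependence unit; any
  cross-family structure (e.g. shared households) would be missed.
* Heritability conversions assume the phenotype scale of analysis; slopes on
  log-transformed values are scale-free but their intercepts are not, and
  identity/log analyses answer different scientific questions (level-
  dependent vs multiplicative familial effects).
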