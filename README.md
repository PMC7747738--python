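# qherit

Quantile-specific familial resemblance for skewed phenotypes.

Classical sib-pair analysis summarises familial resemblance in a single
number: the full-sib regression slope β_FS, the least-squares slope of one
sibling's phenotype on a co-sibling's, which under Falconer's model estimates
(0.5 V_A + 0.25 V_D + V_Ec) / V_P and — when dominance, common environment and
assortative mating are negligible — half the narrow-sense heritability
(h² = 2 β_FS).  For strongly right-skewed traits such as circulating leptin,
a single slope can hide the real structure: the familial effect size may grow
with the level of the phenotype itself ("quantile-dependent expressivity").
`qherit` estimates β_FS at *every* percentile of the phenotype distribution
and tests whether the resulting slope function is flat.

The pipeline, for biostatisticians and genetic epidemiologists working with
flat sibship tables (family id, person id, sex, age, phenotype):

1. **Adjustment** — age/sex adjustment by least squares on the design
   (1, female, age, age², female·age, female·age²), returning residual +
   grand mean so values stay in original units.
2. **Sib pairs** — all ordered within-family pairs by double entry, with the
   adjusted degrees of freedom Σ(kᵢ − 1) used for all inference, and the
   traditional least-squares β_FS.
3. **Quantile regression** — for each percentile τ on the 5–95 grid,
   (a(τ), β_FS(τ)) minimise the check loss Σ ρ_τ(y − a − b x),
   ρ_τ(u) = u(τ − 1{u<0}), solved exactly as a linear program (HiGHS) or by
   a fast compiled IRLS solver; a cluster (sibship) bootstrap refits the
   whole grid per replicate to give the joint variance–covariance matrix of
   the 91 slopes.
4. **Trend tests** — orthogonal (Gram) polynomial contrasts test whether
   β_FS(τ) is constant or changes as a linear/quadratic/cubic function of τ;
   pairwise contrasts such as β_FS(90) − β_FS(10) come with
   covariance-correct SEs and fold ratios; Falconer conversion to h².
5. **Sex matching** — probability–probability (P–P) maps re-plot female and
   male slope functions at equal *concentrations* rather than equal
   percentiles of their separate distributions.
6. **G×E contrasts** — published genotype × condition mean tables are
   re-expressed through the interaction identity
   dC(g₁) − dC(g₂) = dG(c₁) − dG(c₂) as "genotype effect size versus mean
   phenotype level" series; a transcribed corpus of published leptin studies
   ships with the package.
7. **Synthetic cohorts** — a sibship generator with a shared-family variance
   component, sex shift, polynomial age effects and a right-skewing monotone
   transform provides the flat-slope null and the quantile-increasing
   alternative with known truth.

## Worked example

```python
import qherit as q

cfg = q.SyntheticConfig.paper_like(seed=7)      # calibrated skewed cohort
cohort, truth = q.generate(cfg)

adj = q.adjust_phenotype(cohort, cohort.phenotype("leptin"))
pairs = q.build_pairs(cohort, adj, adj)

ols = q.ols_beta_fs(pairs)
h2 = q.falconer_h2(ols.slope, ols.se)
qsf = q.bootstrap_vcv(pairs, q.QuantileGrid.coarse(5), n_boot=200, seed=11)
lin = q.orthogonal_trend_test(qsf, "linear")
con = q.slope_contrast(qsf, 90, 10)
```

This prints (via the corresponding f-strings):

```
cohort: 3076 sibs in 1133 sibships
double-entered pairs: 5948, effective df: 1943
traditional beta_FS: 0.278 +/- 0.022 (p = 5.59e-36)
Falconer h2 = 2*beta_FS: 0.557 +/- 0.044
beta_FS(10) = 0.175, beta_FS(50) = 0.228, beta_FS(90) = 0.584
linear trend: 0.0054 +/- 0.0005 per percentile (p = 1.37e-28)
beta_FS(90) - beta_FS(10) = 0.409 +/- 0.045, fold ratio 3.3 (p = 4.18e-19)
```

Read: a single traditional slope (0.278) would miss that the familial effect
at the 90th percentile is over three times the effect at the 10th — the slope
function rises by ~0.0054 per percentile.  On log-transformed values the same
cohort shows a flat slope function (the generator's skew comes from a
monotone transform of a homoscedastic latent model), mirroring the way
log-transformation masks quantile-dependent effects in real data.

The same steps are available from a shell:

```bash
qherit simulate --seed 7 --out-dir run/
qherit adjust --cohort run/cohort.csv --phenotype leptin --out-dir run/
qherit qreg --cohort run/cohort_adjusted.csv --phenotype leptin_adj \
    --n-boot 1000 --seed 42 --out-dir run/
qherit gxe --study simon2002
```

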