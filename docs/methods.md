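# Methods

## Bias-adjustment model

Let X be an index trait (disease incidence), Y a subsequent trait (survival
among cases), and G a SNP genotype coded additively. The case-only log hazard
ratio β′_GY estimated for G is the sum of its true effect β_GY and an
index-event-bias term proportional to its risk effect β_GX:

    β_GY ≈ β′_GY − b · β_GX.

The derivation assumes no statistical interactions between G, X and the
unmeasured common causes of X and Y, and the regression estimate of b assumes
that true survival effects are uncorrelated with risk effects across the SNP
panel. Violations (e.g. widespread pleiotropy aligned with risk effects)
over- or under-correct; the point-normal "direct effect" component of the
synthetic generator exists to probe exactly that regime.

### Estimators of b

Given harmonized per-SNP pairs (β̂_GX,j, β̂′_GY,j) with standard errors:

- **OLS**: unweighted least squares of β̂′_GY on β̂_GX.
- **WLS**: weights w_j = 1/se²_GY′,j. Standard errors of the slope come from
  the usual weighted normal equations with an estimated scale (the
  statsmodels convention); confidence intervals and p-values use the normal
  approximation rather than the t distribution — at panel sizes of 10⁴–10⁵
  SNPs the difference is nil and it keeps every estimator closed-form.
- **CWLS**: sampling error in β̂_GX attenuates any regression slope towards
  zero (regression dilution). The corrected estimator multiplies the WLS
  slope by

      ĉ = Σ_j w_j β̂²_GX,j / Σ_j w_j (β̂²_GX,j − se²_GX,j),

  the weighted ratio-of-sums dilution correction: the denominator is an
  unbiased estimate of the weighted sum of squared *true* risk effects. Its
  variance is taken as ĉ²·var(b̂_WLS), ignoring the (second-order)
  uncertainty in ĉ itself; at 10⁴ SNPs ĉ's relative sampling error is ~1–2%
  and this simplification costs a few percent of nominal coverage at most
  (the recovery suite measures ≥ 90% empirical coverage of a nominal 95%
  interval). A denominator ≤ 0 means measurement error dominates the risk
  signal; the estimator is then undefined and the fit raises an error rather
  than returning a sign-flipped slope.

An intercept is fitted by default: the bias relation itself is
through-origin, but an intercept absorbs directional pleiotropy and costs
essentially nothing in efficiency; `intercept=False` (CLI
`--through-origin`) forces the origin. Both modes are tested.

### Adjusting a target SNP

`results.adjust(β′_GY, se, β_GX, se_GX)` returns
β_adj = β′_GY − b̂·β_GX with delta-method variance

    se²_adj = se²_GY′ + b̂²·se²_GX + β²_GX·se²_b,

ignoring covariances: the target SNP is one of ~10⁵ contributing to b̂, so
its leverage on the slope is negligible, and the risk and survival datasets
only partially overlap. This is the simplest defensible propagation; it does
not reproduce bootstrap intervals from earlier analyses of the same data.
Note also that adjusting β′_GY = log 0.766 with β_GX = log 5.64 and
b = −0.025 gives an adjusted HR of ≈ 0.80 — the package reports exactly this
arithmetic; a previously published adjusted HR of 113.3 for the same inputs
involved additional corrections that are not part of this model and are not
reproduced here.

### Diagnostics

Whether OLS or WLS is trustworthy is decided from residual diagnostics, so
these are bit-reproducible: internally studentized residuals
r_i/(σ̂√(1−h_ii)) computed on the whitened (weight-multiplied) design with
the same weights as the fit; normal QQ points pair the sorted studentized
residuals with Φ⁻¹((i−0.5)/n) (plotting-position convention (i−0.5)/n);
scale–location pairs (fitted_i, √|r_i|). An exact fit (residual scale at
rounding level) reports all-zero studentized residuals rather than amplified
noise.

## Harmonization and filtering

SNPs are matched across the risk and survival files by identifier only
(positions are carried but never used for matching, since pruned panels are
exchanged as ID lists). Alleles are reconciled in this order: exact match;
effect/other swap (survival beta negated, `flipped=True`); strand complement;
complement plus swap. Palindromic (A/T, C/G) SNPs are dropped by default —
no allele-frequency-based strand inference is attempted, and in a
genome-wide pruned panel the conservative loss is negligible. Duplicate IDs
within a file keep the record with the smallest standard error (file order
breaks ties). Missing optional QC columns (imputation `info`, `n_studies`)
pass their filters with a logged warning, because real risk and survival
files differ in which QC fields they publish. LD pruning requires genotype
data and is out of scope; `filter_snps(keep_list=...)` accepts an externally
pruned SNP list instead.

## Simulation

Per replicate: G_i ~ HWE(maf) additively coded; U_i ~ N(0,1) representing
all non-genetic risk factors; disease with probability
p_i = expit(β0 + β_GX·G_i + β_UX·U_i); for the ascertained cases only,
survival t_i = ((−log v_i)/(λ e^{U_i}))^{1/ρ} with v_i ~ Unif(0,1), i.e. a
Weibull proportional-hazards model with hazard λρt^{ρ−1}e^{U_i}. The
genotype has no survival effect, so the Cox log HR of G among cases (G as
sole predictor, maximum partial likelihood, Breslow ties — continuous times
make ties improbable) is pure collider bias. A grid cell averages this over
replicates; the implied true log HR is observed_log_hr − mean_bias.

Defaults are the motivating IPF scenario: n = 2,000,000 individuals per
replicate, maf = 0.11, β_GX = log 5, prevalence 0.05% (≈1000 cases per
replicate), λ = e^{−12.5}, ρ = 1.7 (survival times on the scale of days,
median ≈ 1260 at U = 0), observed HR 0.766, 1000 replicates, β_UX grid
{0, 2, …, 20} (the grid step is a package choice; the endpoints are the
study conditions). No censoring is generated by default; an administrative
`censor_time` is exposed but off, matching the generating description.

### Numerical choices

- **Intercept calibration.** β0 is solved so that
  E[p] = Σ_g P(g)·∫ expit(β0 + β_GX g + β_UX u)φ(u)du equals the target
  prevalence. The integral uses 201-node Gauss–Hermite quadrature
  (u = √2·x change of variables); at β_UX = 20 the integrand is a near-step
  in u and 201 nodes still resolve it to well within the Monte Carlo
  oracle's resolution (verified against 10⁷-draw MC estimates). The root is
  found by bisection on the monotone map β0 ↦ E[p] over [−2000, 0] with
  xtol 10⁻¹², then verified to satisfy |E[p] − target| ≤ 10⁻⁸·target.
- **Seeding.** Replicates use independent child `SeedSequence` spawns of the
  cell seed; grid cells derive independent seeds (< 2³¹) from the base seed,
  so any cell is reproducible in isolation and identical configs give
  bit-identical tables.
- **Failure containment.** A replicate with too few cases or a failed Cox
  fit is skipped and logged; a cell with > 10% failures is flagged
  unreliable in the output.

## Synthetic summary statistics

The generator emulates the *structure* of two-trait GWAS summary data with a
known bias slope: true risk effects N(0, τ²_gx); direct survival effects
point-normal (nonzero with probability `prop_direct`, then N(0, τ²_gy)),
independent of risk effects; observed effects add N(0, se²) noise with
per-SNP SEs uniform in their ranges. Defaults — τ_gx = 0.08,
se_GX ∈ (0.03, 0.07), se_GY ∈ (0.10, 0.20), prop_direct = 0.1,
τ_gy = 0.05, b_true = −0.025, n = 140,092 SNPs — give effect and error
scales of a moderately sized case-control GWAS with a much smaller survival
arm, and an expected WLS attenuation factor of ≈ 0.71, large enough that
dilution and its correction are cleanly measurable. What it does *not*
emulate: LD between SNPs (pruned panels are near-independent by
construction), allele-frequency-dependent standard errors, correlated
risk/survival sampling noise from overlapping samples, and pleiotropy
correlated with risk effects. Passing recovery tests therefore show the
estimators behave correctly under their stated assumptions, not that those
assumptions hold in any particular real dataset.

## Problem sizes in the automated checks

The test suite runs most components at reduced scale (2×10⁵ individuals, 20
replicates; panels of 3–30×10³ SNPs) and the end-to-end scientific checks at
the full 2×10⁶ individuals with 200 replicates (a fifth of the default 1000,
which only shrinks Monte Carlo SEs, not means). `scripts/acceptance.py` uses
200 replicates per simulation cell, 50 replicates per case-count check and a
10⁷-draw prevalence oracle. Full-scale runs remain one flag away
(`--reps 1000`).

## Known limitations

- CWLS intervals slightly undercover (ĉ uncertainty ignored); a bootstrap
  over SNPs would fix this at ~100× the cost.
- No strand inference for palindromic SNPs; they are simply dropped.
- The real-data application (consortium summary statistics plus a pruned SNP
  list) is supported through the CLI but ships no data; published slope
  estimates from those files are not reproducible offline.
- MR-RAPS and Slope-hunter, alternative slope estimators used in the
  literature, are deliberately not re-implemented.
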