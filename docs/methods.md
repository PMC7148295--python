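# Methods

## The estimand and the growth-rate summary

Tumour volume in these models grows approximately exponentially over the
first weeks after implant, so each animal's series is reduced to the slope
*b* of an ordinary least-squares fit of `log10(volume)` on study day
(`volume = width²·length/2`, mm³). The treatment effect of interest is the
difference in mean growth rate, treated − control, in log10 mm³/day;
negative values mean inhibition. Two data conventions stabilise the fit:

* **day cap (default 30)** — later measurements are dropped, so plateau or
  regression dynamics past the exponential phase do not bias the slope;
* **volume floor (default 50 mm³)** — readings below the floor are clamped
  to it before the log transform, reflecting the calliper detection limit.
  The cap is applied first, then the floor; the two operations commute.

Fits need at least three points (slope + intercept + one residual df).
Animals with fewer usable points raise an explicit error rather than being
silently dropped; a series entirely at the floor returns a zero slope
flagged `degenerate`. Fits are unweighted; days may be non-integer; no
interpolation is performed.

## The data-generating model

`simulate_experiment` draws per-animal rates with three variance layers:

| parameter | meaning | default | unit |
|---|---|---|---|
| `baseline_mean` | mean control growth rate | 0.1242 | log10 mm³/day |
| `baseline_sd` | animal-level SD | 0.03916 | log10 mm³/day |
| `batch_sd_prop` | batch-effect SD ÷ baseline mean | 0.20 | proportion |
| `gri` | growth-rate inhibition (mean effect ÷ baseline mean) | 0 | proportion |
| `gri_sd_prop` | between-batch SD of the effect ÷ mean effect | 0 | proportion |
| `n_batches` × `n_control_per_batch`/`n_treated_per_batch` | layout | 3 × 5/5 | animals |

Batch *j* receives `u_j ~ N(0, (batch_sd_prop·baseline_mean)²)` added to
both arms; the treated arm of batch *j* is shifted by
`−Δ_j, Δ_j ~ N(gri·m, (gri_sd_prop·gri·m)²)` with `m = baseline_mean`.
The defaults are the historic vehicle population used to calibrate the
methodology (mean 0.1242, SD 0.03916); the operating-characteristic
studies use the MC38-like baseline 0.105 ± 0.026. Batch variation is
parameterised on the **SD scale** (batch SD as a proportion of the baseline
mean): it keeps the parameter dimensionless and matches how the effect
heterogeneity is specified; a variance-scale reading would make even the
smallest sweep value a larger-than-animal-level perturbation.

What the generator deliberately does **not** emulate: longitudinal volume
trajectories (rates are drawn directly, so measurement-level noise,
dropout and humane-endpoint censoring are absent), batch-by-group shifts
beyond the effect heterogeneity term, non-normal rate distributions, and
unequal group sizes within a batch (supported by the estimators, not swept
by the engine). Passing simulation checks therefore demonstrates the
statistical behaviour of the estimators under the stated Gaussian
three-layer model, not robustness to those real-data features.

## The four estimators

All four consume the same per-animal rate table and report the
treated−control difference, its SE, a test statistic, a two-sided p-value
and variance components.

**Pooled.** Equal-variance two-sample *t*-test (equivalently OLS of rate on
group), df = N − 2. Ignoring the batch structure inflates the residual
variance when batches differ, which simultaneously deflates type I error
and power — the central argument against pooling.

**Fixed effects.** Full factorial model (treatment + batch + interaction).
The estimate is the marginal (least-squares) mean difference — batches
weighted equally regardless of size — and significance is the type III
F-test of the treatment main effect with sum-to-zero contrasts. For two
groups this F equals the squared *t* of the marginal-mean contrast in the
cell-means parameterisation, so both are computed in closed form from cell
means; equivalence with a formula-based type III ANOVA is enforced in the
test suite on unbalanced data.

**Random effects (mixed model).** Treatment fixed; batch and
batch-by-treatment random. The likelihood is profiled over the residual
variance and maximised over the two variance ratios (bounded at zero, two
starts, analytic gradients); the treatment contrast is tested with a
*t*-statistic on Satterthwaite degrees of freedom computed from the
expected information of the variance parameters. Components estimated at
the zero bound are excluded from the Satterthwaite sum — equivalent to
differentiating on the SD scale, where the chain-rule factor vanishes at
zero — so the df adapts toward the residual df as the structure empties;
such fits are reported with a `boundary` flag, not as errors.

The fit maximises the **full (ML) likelihood by default** rather than
REML. This was a genuinely open choice, settled empirically: with three
batches and five animals per arm, the REML/Satterthwaite combination is
conservative under the null (type I error ≈ 3.5% at a nominal 5%, driven
by replicates where the interaction component truncates at zero), while
ML/Satterthwaite holds the nominal level — the calibration the methodology
is reported to achieve. Both variants are exposed (`reml=` flag) and both
are validated against lmerTest to ~1e-4 in p-values.

**Random-effects meta-analysis.** Stage one computes per-batch mean
differences `T_i` and sampling variances `v_i² = s_c²/n_c + s_t²/n_t`;
stage two estimates the between-batch variance τ² by REML (bounded 1-D
likelihood maximisation, floored at zero) and pools with inverse-variance
weights `w_i = 1/(v_i² + τ²)`. The test is a *z*-test, which with three
batches is mildly liberal — the engine reproduces a ≈6–7% null rejection
rate at the 5% threshold, and that liberality is precisely why the mixed
model is preferred when both are available.

**Variance-model LRT.** A likelihood-ratio test for level-specific versus
shared residual variance (levels of treatment or batch), with the mean
structure held fixed in both models; Gaussian ML fits via a short iterated
weighted-least-squares fixed point, chi-squared reference on
`n_levels − 1` df. Used to judge whether treated arms (or historic
studies) differ in spread, e.g. detecting 3-fold variance ratios.

## Monte-Carlo engine

Scenario grids sweep batch variation, inhibition, effect heterogeneity,
group size and number of batches around a base configuration; each cell
runs `n_reps` replicates (`n_repeats` independent repetitions), every
replicate seeded as `SeedSequence(root, spawn_key=(cell, repeat, rep))` —
results are independent of execution order and any replicate can be
replayed alone; child seeds stay below 2³¹. Simulated data is shared
across methods within a replicate, mirroring how the methods would face
the same experiment. FPR grids require `gri = 0` everywhere, FNR grids
`gri > 0`; rates carry Wilson 95% intervals from the pooled replicate
counts. Non-converged mixed fits count as non-significant and are tallied
in an `n_failures` column (none have been observed in the shipped grids).

The single-batch sample-size search uses the exact noncentral-*t* power of
the two-sided two-sample *t*-test (standardised effect
`d = gri·mean/SD`), returning the smallest per-group n reaching the target
power; deep-tail probability terms that underflow are treated as zero.
Animal-budget helpers multiply out design totals and report the percent
saving to the nearest integer.

## Numerical choices

* Variance ratios are declared at the boundary below 1e-8; REML τ² snaps
  to zero when the bound is at least as good as the interior optimum.
* Residual SDs of growth fits below 1e-12 are reported as exactly 0
  (perfect collinearity up to float noise).
* Satterthwaite df is floored at 1; a non-finite or non-positive
  denominator falls back to the residual df.
* The heteroscedastic ML fixed point iterates to 1e-12 relative change;
  the LRT statistic is clamped at ≥ 0.
* The significance threshold is two-sided 0.05 throughout; the engine
  accepts `alpha` up to and including 1 (the saturation case is useful for
  validating the tallying).

## Problem sizes

The shipped Monte-Carlo checks run at desk scale, chosen to keep each
claim decidable within its Monte-Carlo error: calibration and ordering
checks use 1000–2000 replicates per cell over 2–4 grid cells;
`scripts/acceptance.py` uses 8000 replicates per cell for the
meta-analysis sweep (10 cells, SE ≈ 0.09 percentage points) and 2000 per
cell for the regression methods (3 cells). Denser sweeps or larger
replicate counts move these estimates only within their Monte-Carlo error.

## Known limitations

* Exactly two arms (`control`/`treated`); multi-arm studies reduce to
  pairwise contrasts against control.
* No covariates in any model, and no unequal-variance pooled *t*-test.
* The meta-analysis needs ≥2 animals per group per batch to estimate
  `v_i²`; singleton cells are a structural error rather than being merged.
* The mixed model's Satterthwaite df uses expected (not observed)
  information; differences against lmerTest are ≤1e-3 in p on validation
  datasets but are not formally bounded.
* Growth-rate fits assume homoscedastic Gaussian error on the log scale;
  no Gompertz or other saturating growth model is offered.
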