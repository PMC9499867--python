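# Methods

This note documents the models, conventions and numerical choices behind
`preclad`, and what the synthetic-data experiments do and do not establish.

## Preprocessing and standardization

Concentration biomarkers (plasma p-tau181/217/231, GFAP, NfL; CSF
M-p-tau181) are log₁₀-transformed before any modelling; the CSF and plasma
Aβ42/40 ratios are left on their natural scale. Classification uses strict
inequalities exactly as printed on the assay scales: amyloid-positive below a
CSF Aβ42/40 of 0.071, tau-positive above 24 pg/ml of CSF M-p-tau181;
PET staging at 12 and 30 Centiloids; a CSF-normal/PET-high cell
(Aβ42/40 ≥ 0.071 with ≥ 30 CL) does not belong to the three-group CSF/PET
system and is reported as `unclassified_discordant`, never merged.

Trajectory z-scores are built in a fixed order: transform → OLS
residualization on intercept + age + sex (whole-sample fit, sex coded 0/1) →
standardization against the reference stratum of participants with
CSF Aβ42/40 > 0.1, using the sample SD (n−1). The residualize-then-standardize
order is a modelling choice (the alternative order is exposed as
`RunConfig.residualize_before_zscore`); with either order the reference subset
has mean 0 and SD 1 by construction. Missing data are handled complete-case
per analysis; nothing is imputed.

## Robust locally weighted regression

The smoother is classic robust LOWESS with a **count-based span**: each fit is
a local linear regression over the `span_points` (default 300) nearest
observations with tricube distance weights, followed by 5 robust re-weighting
passes in which residuals are scaled by 6·median|r| and down-weighted with the
bisquare function (weight 0 at or beyond the scale). Boundary neighbourhoods
are asymmetric; no reflection. Ties in the abscissa are supported, including
the degenerate case of a neighbourhood collapsing onto one abscissa (weighted
mean fallback over the whole tie run). When the median absolute residual falls
to rounding level relative to the response magnitude (≤ 1e-9·max|y|), the fit
is treated as interpolating and re-weighting stops — otherwise bisquare
weights would be driven by floating-point noise on noiseless data.

Because the abscissae are sorted, each neighbourhood is a contiguous window
found by a two-pointer sweep; the hot loop is compiled with numba (a
vectorized numpy fallback implements the identical arithmetic). The
implementation was cross-checked against R's independent `lowess`
(`f = span/n`, `iter = 5`, `delta = 0`), which reproduces the package's fitted
curves to ~4e-10 on cohort-sized problems, and against a per-point
weighted-least-squares oracle in the test suite (1e-6 tolerance).

## Bootstrapped trajectories and abnormality crossings

For each biomarker, z (oriented so that movement in the pathological direction
is positive — relevant for the falling Aβ42/40 ratio) is modelled along a
proxy of progression: PET Centiloids, or the CSF Aβ42/40 ratio with its axis
inverted so progression runs from high to low ratio. Each of 1,000 bootstrap
replicates resamples the complete pairs with replacement (size n, ordinary
bootstrap), sorts by proxy, smooths, averages fitted values over tied proxy
values, and interpolates linearly onto the grid of proxy values observed in
the original sample. The final model is the pointwise mean across replicates;
the envelope is the pointwise 2.5/97.5 percentile band. A span exceeding the
available n is clamped to n with a logged warning. Runs are deterministic
given a seed (per-biomarker child streams).

The abnormality crossing for threshold z* (1.5 or 2.0) is the first grid
location, in the analysis direction, where the mean trajectory reaches z*,
linearly interpolated between bracketing grid points; it is never extrapolated
beyond the observed proxy range, and "never crosses" is an explicit result.
Crossing confidence intervals are percentile intervals of per-replicate
crossings, reported together with the number of replicates that crossed —
near the sparse right edge of the Centiloid range a minority of replicates can
cross even when the mean curve does not, and a mean-curve crossing located in
that sparse edge region should be read with the same caution.

### Estimator accuracy

Parameter-recovery experiments (20 seeded n=400 cohorts, default noise) show
the span-300 estimator carries an intrinsic smoothing bias of about +3
Centiloids at a true 2-SD crossing of ~26 CL under a right-skewed burden
distribution (the local-linear window at the rise is dominated by the
low-burden bulk), with a sampling SD of about 4 CL. The SD is driven by the
reference standardization itself: z-spread inside the reference stratum is 1
by construction, so per-subject z-noise is ~1 SD regardless of assay precision,
while the full trajectory spans only ~3.5–4 z. **Crossing order** across
biomarkers is far more stable than crossing location, because the smoothing
bias is shared; the recovery suite therefore treats ordering as the robust
deliverable and location as accurate to roughly ±5 CL (1–1.5 SD) per cohort.

## Effect sizes and ANCOVA

Cohen's *d* uses the pooled-SD convention with a normal-approximation 95% CI,
se(d) = √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b))); the accompanying p-value is
the pooled-variance two-sample t-test. For markers that fall with pathology
the oriented d (positive = more pathological) is reported alongside the raw
signed value. The ANCOVA omnibus test is the extra-sum-of-squares F for the
group factor over age + sex; Tukey post-hoc contrasts compare adjusted group
means (differences of dummy coefficients, i.e. means at covariate means) with
studentized-range p-values at the model's residual degrees of freedom. With
two groups the Tukey p equals the unadjusted contrast p.

## Discrimination

AUC is the Mann–Whitney statistic with tied pairs counted ½; variance and the
covariance of paired AUCs come from DeLong placement values with sample
(n−1) covariances; CIs are Wald intervals on the logit scale, clipped to
[0,1]. Rank-equivalent score vectors give a zero-variance difference and are
reported as ΔAUC = 0, p = 1 with a degeneracy flag. Combined models are
in-sample maximum-likelihood logistic regressions (apparent AUC, no
cross-validation — matching how such tables are usually computed); complete
or quasi-complete separation is detected (non-convergence, non-finite or
extreme standardized coefficients) and answered with a Firth-type penalized
fit (Jeffreys-prior score correction, step-halved Newton iterations), flagged
in the output. DeLong on nested models (base vs base + biomarker) is known to
be conservative; it is used as-is because that is the comparison the report
reproduces. Operating points: the Youden cutoff maximizes sensitivity +
specificity − 1 over observed scores (ties broken toward higher specificity);
the fixed-sensitivity point is the largest cutoff whose sensitivity still
reaches 85% (the minimum score always attains sensitivity 1, so a point
always exists; with very few positives the attained sensitivity may overshoot
the target). Benjamini–Hochberg FDR adjustment is applied within each
stratum's family of model-vs-base comparisons.

## Longitudinal change

The cognitive composite is the unweighted mean of four subtest z-scores
(FCSRT immediate total recall, Logical Memory delayed recall, Coding,
Semantic fluency), standardized to the baseline biomarker-negative (A−T−)
subgroup; visit-2 composites reuse the baseline reference statistics so both
visits share one scale. MMSE is excluded (insensitive in preclinical
cohorts). Annualized change is (v₂ − v₁)/Δt with Δt in 365.25-day years from
calendar dates (numeric year inputs are also accepted). Change regressions
adjust for age and sex, plus education for the cognitive outcome; the
amyloid-status interaction model and the amyloid-stratified subset
regressions are both produced, as is the <30-Centiloid sensitivity subset for
the PET outcome. Raw and BH-FDR-adjusted p-values are reported side by side.

## Synthetic cohort generator

The generator is calibrated to the structure of a middle-aged, risk-enriched,
cognitively unimpaired cohort: n = 397, age 61.1 ± 4.67, ~61% women, ~50%
APOE-ε4 carriers (enriched by design), ~34% amyloid-positive by CSF.

* **Latent burden.** Each participant belongs to a "no-pathology" component
  (Centiloids ~ N(−1, 5.5)) or a pathological component with a gamma tail
  (shape 0.51, scale 35.9 — solved so that, at the default mixture weight of
  0.36, about 15% of the cohort exceeds 12 CL and about 7–8% exceeds 30 CL,
  matching the staging fractions such cohorts report). Membership probability
  rises with age (+0.10/yr on the logit) and APOE-ε4 (+1.6), giving the base
  risk-factor model its realistic discriminative value (AUC ≈ 0.6–0.67).
* **CSF.** The Aβ42/40 ratio is a falling sigmoid of latent burden (plateau
  0.118, floor 0.046, width 3.5 CL) times lognormal noise (CV 12%); its
  midpoint is **calibrated at generation time** (bisection) so the realized
  positive fraction hits the configured target for the drawn sample. CSF
  M-p-tau181 rises later (midpoint 32 CL), reproducing the observed
  AT cell structure (~249/104/31/13 of 397).
* **Plasma markers.** Each marker follows a sigmoid in log₁₀ space —
  `log10(level) = log10(baseline) + log10(fold) · expit((CL − midpoint)/width)`
  — times lognormal noise and small age/sex effects. Midpoints are staggered
  (p-tau231 earliest at 21 CL, then p-tau217 at 33, GFAP at 40 with a larger
  threshold distance; p-tau181, NfL and Aβ42/40 have late midpoints or small
  fold changes and never reach 2 SD), so the generator's 2-SD ground-truth
  crossings land at ≈ 25.8, 36.9 and 52.9 CL.
* **Follow-up.** Visit-2 Centiloids accumulate at a burden-dependent rate
  (~0.25–2.8 CL/yr); four cognitive subtests at two visits decline with a
  configurable coupling between baseline p-tau231 and amyloid status
  (`interaction_strength`, PACC-z/yr per SD of log p-tau231; default 0.1),
  with realistic measurement noise and 3.3 ± 0.3–0.4-year intervals;
  follow-up subsets of ~214 (cognition) and ~145 (PET) participants.
* **Seeding.** One master seed expands into fixed named child streams
  (demographics, latent burden, CSF, PET, one per biomarker, follow-up), so
  adding a biomarker never perturbs the others; everything is reproducible
  byte-for-byte.

**Ground truth.** `ground_truth_crossing` standardizes the noiseless sigmoid
with reference-stratum statistics obtained from a large (n = 120,000)
internally-seeded draw of the latent/CSF/noise model — analytic up to
negligible Monte-Carlo error — and locates threshold crossings by bisection.
Age/sex effects are omitted there because the pipeline removes them by
residualization.

**What the generator does not emulate:** assay plate/batch effects, platform
differences, non-lognormal outliers, informative dropout at follow-up, and
voxel-level imaging. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the stated model, not
that real cohorts satisfy that model.

## Problem sizes and determinism

The test suite runs the recovery experiments at the study's own scale
(n = 400, 1,000 bootstraps, 20 seeds) and the null-calibration simulations at
1,000–2,000 replicates; the acceptance script uses one default cohort
(n = 397) with 1,000 bootstraps. Pipeline outputs contain no timestamps, so
identical config + seed reproduces byte-identical report bundles.
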