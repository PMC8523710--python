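# Methods

## The study design being emulated

The pipeline targets a two-session pharmacological memory study: encoding of
60 pictures (30 emotionally negative, 30 neutral), each shown once in each
of three consecutive runs (3-s presentations, 4 ± 1 s jittered fixation,
TR = 2 s), with a drug manipulation (placebo vs yohimbine) timed so that
noradrenergic arousal rises *after* encoding, during early consolidation.
Recognition is tested 1 or 28 days later in three runs containing the 60
old pictures and 60 new pictures matched pairwise to old items by emotion,
answered on a 4-point confidence scale. The four between-subject cells
(drug × delay) hold 26 subjects each by default, balanced for sex.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions above. BOLD volumes follow a forward model that mirrors the
analysis GLM's assumptions:

* **Signal.** Each trial contributes an amplitude image convolved with the
  canonical double-gamma HRF. The amplitude image is a shared baseline
  response (1.0, i.e. amplitudes are in percent-signal-like units) plus an
  ROI-level old-minus-new shift at recognition (± delta/2) plus an
  item-specific multivariate pattern scaled by `pattern_scale` (default 3).
* **Item patterns.** Gaussian voxel vectors normalized to unit RMS per
  voxel. The recognition pattern of old item *i* is
  r·(encoding pattern) + √(1 − r²)·(independent pattern), applied voxel-wise
  with r taken from the planted per-ROI, per-cell ERS value (0 outside
  effect ROIs), which makes the expected encoding→test correlation inside
  an ROI exactly r. New items get independent patterns. This construction
  gives analytic control of planted reinstatement.
* **Nuisance.** Two cosine drift components per run below the 1/128 Hz
  cutoff (coefficient SD 1.0), AR(1) Gaussian scan noise (ρ = 0.3,
  stationary SD 1.0 — noise on the same scale as the baseline response),
  and one shared AR(1) fluctuation per ROI (SD 0.7) so seed eigenvariates
  summarize something real. The PPI effect is planted by adding
  gain · (seed-ROI fluctuation) · (HRF-convolved old-trial train) to target
  ROI voxels during recognition.
* **Behavior.** Equal-variance signal detection: evidence ~ N(d′, 1) for
  old and N(0, 1) for new items, a decision criterion λ (default 1.7, which
  yields the high-hit / low-false-alarm regime typical of picture
  recognition), and confidence criteria at λ ± 0.5 mapping evidence to the
  4-point scale. The default cell d′ values decline from ≈3.1
  (1d) to ≈1.9 (28d) under placebo but only to ≈2.45 under yohimbine, with
  a smaller decline for negative items; the implied drug × delay contrast
  (≈0.65) and the emotion × delay gap (≈0.4) match the magnitudes such
  studies report.
* **Between-subject heterogeneity.** Planted effects receive per-subject
  Gaussian jitter (SD 0.2 on amplitudes and coupling gains, 0.05 on r,
  0.25 on d′) so group tests face realistic subject variance rather than
  pure estimation noise.

What the generator does **not** emulate: physiological (cardiac or
respiratory) noise, head motion, spatial heteroscedasticity, anatomically
realistic geometry, non-Gaussian pattern structure, or response-time
behavior. Passing tests therefore demonstrate the estimators' correctness
and calibration under the stated model, not robustness to every artifact of
real acquisitions.

The default grid is 24³ voxels at a nominal 3 mm (most validation runs use
16³ or 12³); three disjoint spherical ROIs (radius ≈ grid/8) act as a
hippocampus-like target, an IFG-like neocortical region with the reversed
univariate pattern, and a null control region.

## First-level model

One GLM spans all six runs (three encoding, three recognition) with per-run
regressors, per-run cosine drift blocks, and per-run constants. Condition
mode groups events by emotion at encoding and emotion × oldness at
recognition; trial-wise mode gives every trial its own regressor. (The
original design additionally contained item categories that this artifact
does not simulate, so the condition-mode recognition block has 2 × 2 rather
than 8 regressors per the same per-emotion-and-category rule.) Serial
correlation is handled with a single pooled AR(1) coefficient: OLS
residuals from an ~1024-voxel subsample give the pooled lag-1
autocorrelation, both sides of the model are filtered by the AR(1)
square-root filter within runs, and the whitened system is solved by
Cholesky-factored normal equations (this is also what the oracle-equivalence
test asserts, to 1e-8). The pooled-ρ choice (rather than voxel-wise AR
models) trades a little local adaptivity for stability at desk scale.
Trial patterns are β/SE t-values, computed from unsmoothed data; univariate
contrasts use 8-mm-FWHM smoothed data. No HRF derivatives, motion
regressors, or slice-timing correction (out of scope).

## Searchlight ERS

Spheres are integer-offset balls of radius 3 (123 voxels in the interior),
clipped to the analysis mask; centers whose sphere holds fewer than 10
voxels are dropped. Per-sphere Pearson sums are evaluated for all centers
simultaneously by FFT-convolving voxel-wise product maps with the sphere
kernel — numerically identical to looping over spheres (the test suite
checks this against an explicit loop) but fast enough for whole-brain maps
per subject in well under a second. Fisher z uses atanh with clipping at
1 − 1e-7 so perfect correlations stay finite without materially moving
ordinary values. z-values are averaged over items before group analysis
(z-then-average); the trial-specific ENS uses exactly the one matched new
item per old item, as the pairing table specifies. The ERS
parameter-recovery check restricts the searchlight to the ROI so sphere
membership does not dilute the planted in-ROI correlation with surrounding
null voxels; whole-brain maps accept that dilution, which attenuates but
never reverses effects.

## PPI

The seed is the first eigenvariate (leading left singular vector, sign-fixed
to correlate positively with the ROI, unit variance) of high-passed,
smoothed recognition data in the seed ROI. The psychological regressor is
the old(+1)/new(−1) event train convolved with the HRF — convolved so both
factors live on the BOLD time scale — and the interaction is the literal
element-wise product at scan resolution, with no hemodynamic deconvolution
of the seed (the deconvolution-based variant is a known alternative; the
plain product is what this pipeline implements and tests). The design also
carries an HRF-convolved all-events confound: a task-responsive seed shares
the common stimulus response with every voxel, and without that column the
shared component leaks into the interaction estimate (we observed spurious
group-level PPI interactions in null regions when it was omitted).

## Group inference

Within-subject factors (old vs new, recognition vs encoding, EOS vs ENS)
are collapsed to per-subject difference maps, so a between-subjects 2×2
ANOVA per voxel tests the three-way pattern; the signed interaction t uses
the contrast (PLAC: 1d − 28d) − (YOH: 1d − 28d) with pooled within-cell
variance (df = N − 4). ROI familywise error is controlled by max-statistic
permutation: maps are residualized against the main-effects design,
residual rows are permuted (Freedman–Lane), and the observed ROI peak |t|
is ranked in the permutation maxima, p = (1 + #{max ≥ obs})/(n_perm + 1).
When fewer distinct label arrangements than n_perm exist, all arrangements
are enumerated (applied directly to subject rows) and the identity term
makes the p-value exact with resolution 1/#arrangements. Clusters are
formed at two-sided p < 0.005 on |t|; peak-level inference is primary and
extent is descriptive. Bonferroni across ROIs is applied on request. The
default n_perm is 1000 (validation runs use 200–500); a seed is mandatory.

## Behavioral statistics

d′ uses the log-linear correction (+0.5 to hit/FA counts, +1 to item
counts) by default — chosen because it is continuous and keeps d′ finite at
ceiling, with "clamp" and "none" available. Confidence weights default to
{definite: 1.0, rather: 0.5}; no canonical weighting transform exists, so
the map is configurable and nothing in the package treats this default as
authoritative. The factorial interaction is an effect-coded least-squares
fit with full-vs-reduced sums of squares (type-III style, valid for
unbalanced cells), reported with partial η² = SS_effect/(SS_effect +
SS_error); `statsmodels` serves as an independent cross-check in the tests,
not as the implementation, because calibration studies run thousands of
fits. Subject-level factorial ANOVA stands in for trial-level mixed models,
which are out of scope; the interaction contrast is the same quantity of
interest.

## Numerical choices and degenerate inputs

* Rank-deficient designs raise errors naming the collinear columns (pivoted
  QR); all-zero contrasts and weights touching nuisance columns are
  rejected/warned.
* Zero-variance voxels yield t = 0 rather than NaN; constant ROIs and
  constant samples raise degenerate-data errors where a statistic is
  undefined, with the one contract exception t = 0 for identical constant
  samples in Welch's test.
* Spheres with fewer than 3 voxels cannot support Pearson correlation and
  fall under the 10-voxel occupancy floor anyway.
* All grids index voxels 0-based; tables report coordinates through the
  mask's affine (synthetic grids use a scaled identity at 3 mm).
* TSVs are tab-separated UTF-8 with "n/a" for missing values.

## Problem sizes used in validation

Chosen as the package's own desk-scale working points: detection of the
planted drug × delay structure uses 20 cohorts of 8 subjects per cell on a
16³ grid with 500 permutations; ERS recovery uses 8 subjects per planted
correlation level at near-zero noise (the algebraic self-check regime);
FWE calibration uses 500 null cohorts of 4 subjects per cell with 200
permutations; PPI recovery uses 20 cohorts of 8 subjects on 12³ grids; the
behavioral calibration uses 2000 null simulations and 26 subjects per cell
for power. `scripts/acceptance.py` re-runs the same computations at the
sizes printed in its source and reports every number it computes.

## Known limitations

The permutation difference-map ANOVA is a principled stand-in for
flexible-factorial models with nonsphericity corrections, not a bit-level
reproduction of them; whole-brain random-field FWE, TFCE, covariate
modeling, ROC-model fitting, mixed-effects estimation, and MRI
preprocessing (realignment, normalization) are deliberately out of scope.
Cross-trial ERS at large grids is chunked but remains the most expensive
variant. Simulated noise is Gaussian AR(1); heavy-tailed or structured
noise may degrade calibration in ways these tests do not measure.
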