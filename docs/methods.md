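# Methods

`boldpost` implements the computational core of a harmonized fMRI
post-processing workflow: it takes *minimally preprocessed* 4D BOLD
images (already motion-corrected, resampled to a common space) and
carries them through additional preprocessing, single-subject feature
extraction, quality control, and mixed-effects group inference, with a
planner that deduplicates shared steps across a multiverse of setting
combinations. This note records the models, the defaults, the numerical
choices, and what the synthetic tests do and do not demonstrate.

## Post-processing chain

The chain runs in a fixed order: spatial smoothing, grand-mean scaling,
nonaggressive ICA denoising, temporal filtering. The order matters (the
steps do not commute) and is asserted by test rather than assumed.

**Smoothing to a target FWHM.** Rather than applying a fixed kernel,
the image is smoothed *to* a target smoothness (default 6 mm FWHM), so
data with different intrinsic smoothness are harmonized. Smoothness is
estimated with the classic Gaussian-random-field first-difference
estimator: for a field with Gaussian autocorrelation
`rho(d) = exp(-d^2 / (4 sigma^2))`, the lag-1 spatial autocorrelation
along an axis gives `sigma^2 = dx^2 / (-4 ln rho)`, and the per-axis
FWHM values are combined by geometric mean. The smoothing loop applies
mask-constrained Gaussian passes (kernel weights renormalized over
in-mask voxels so non-brain intensities never leak in), with each step
width chosen from the convolution identity
`FWHM_out^2 = FWHM_in^2 + FWHM_step^2`, capped at 50 iterations,
converging to within 5% of the target. Because masked smoothing near
edges and non-Gaussian intrinsic structure break the exact identity,
each step is applied as a trial: an overshooting trial is discarded
and retried with a quadrature-corrected smaller width, so the target
is approached without permanent overshoot. An input already smoother than
the target is returned unchanged with a warning — smoothing cannot be
undone. The autocorrelation-based variant of the estimator used by some
packages is not implemented; the classic estimator is the documented
choice and the one the tests calibrate against. Estimates on
unsmoothed white noise are sub-voxel by construction (the lag-1
correlation is near zero); a floor keeps them positive.

**Grand-mean scaling.** The grand mean (mean over all in-mask voxels
and time points) is set to 10,000 by a single multiplicative factor.
The same factor is applied to every confound column. This includes
motion-derived confounds with physical units; scaling them preserves
the regression geometry (which is scale-invariant per column) and keeps
image and confounds on one consistent scale, but users exporting the
processed confounds should know all columns are scaled.

**Nonaggressive ICA denoising.** Given an external ICA decomposition
(mixing matrix plus noise labels — component estimation and
classification are out of scope), each voxel's demeaned series is
regressed jointly on *all* component time courses; only the noise
components' fitted contributions are subtracted, and the voxel mean is
restored. Because weights come from the joint fit, variance shared
between signal and noise components is retained. Demeaning before the
fit and restoring the mean afterwards keeps the grand-mean target
intact through denoising. One caveat discovered in testing: the
folklore property "denoising never increases voxel variance" is only
guaranteed when component time courses are mutually orthogonal (the
ICA regime); with strongly correlated columns the cross term can raise
residual variance at some voxels. The property test therefore
orthogonalizes its mixing fixture.

**Temporal filtering.** Two filters are provided. The frequency filter
is an ideal DFT-domain filter: bins strictly outside the passband are
zeroed, a bin exactly at a cutoff is retained (the inclusive-band
convention of the low-frequency-fluctuation literature), a highpass
removes the DC bin, a pure lowpass keeps it. The Gaussian-weighted
filter (the FEAT-style default, 128 s FWHM) subtracts a
Gaussian-weighted local mean with `sigma` (frames) =
`FWHM / (2 sqrt(2 ln 2)) / TR`, weights renormalized at the series
edges, followed by removal of the residual mean so the output mean is
exactly zero. At the *chain* level each series' pre-filter mean is
restored after filtering (for image voxels and confound columns alike,
so the operator identity between the two sides is preserved): a
highpassed image keeps its grand-mean target instead of collapsing to
zero mean. Its transfer function rolls off gradually: a 0.05 Hz
oscillation under the 128 s highpass keeps ~99.9% of its amplitude in
our tests, while a linear drift is suppressed to a few percent. Both
filters are linear operators applied identically to image voxels and
confound columns.

**Confound consistency.** Any temporal operation applied to the image
(scaling, denoising, filtering) is applied to the confound table too.
Otherwise, regressing raw confounds out of filtered data re-introduces
the removed low-frequency variance through the confounds' own drift
content. The operational statement — feeding a confound column through
the image path yields exactly the processed confound column — is
verified to 1e-8, and the package's integration test shows both
directions: with chain-processed confounds the residual image carries
no sub-cutoff power (fraction < 1e-6), with raw confounds the drift
returns (> 1e-4). Note that drift-like confound columns are themselves
annihilated by denoise+highpass processing; selecting them afterwards
correctly raises a rank-deficiency error rather than silently fitting
a zero regressor.

## Features

Six single-subject features are computed from the post-processed image.
All regression-based features share one OLS core, and per-feature
constraints are enforced: atlas matrices must come from unsmoothed
data, and ReHo/fALFF are computed before smoothing (smoothing, if
requested, applies to their output maps).

- **Task GLM**: condition boxcars sampled on the frame grid, convolved
  with a double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
  dispersions, undershoot ratio 1/6, normalized to peak 1 — the
  de-facto parameters of the major packages), plus an intercept.
  Prewhitening is deliberately omitted: the fit is plain OLS, for which
  the stated dof (t − rank) is exact under white noise; with
  autocorrelated noise the first-level variances are optimistic, which
  the group stage partly absorbs into between-subject variance.
- **Seed connectivity**: per-voxel OLS on [intercept, seed mean
  series]; effect and sampling variance of the seed coefficient,
  dof = t − 2. Seed series below the minimum-coverage threshold
  (default 0.5, always explicit in configuration) yield a missing
  feature, not an error.
- **Dual regression**: stage 1 regresses each frame's in-mask voxel
  vector on the spatially demeaned template maps plus an intercept
  (a spatially constant map would duplicate the intercept; in that case
  the raw map takes the intercept's place, so a single all-ones
  template recovers the global-mean signal); stage 2 regresses each
  voxel's series on the stage-1 time series plus an intercept,
  dof = t − k − 1. Stage-1 time series are used raw (no variance
  normalization) — the variance-normalized variant is a documented
  alternative, not implemented.
- **Atlas matrix**: region mean series by masked averaging, pairwise
  Pearson correlations; regions under the coverage threshold produce
  missing (NaN) rows/columns rather than zeros.
- **ReHo**: Kendall's coefficient of concordance between each voxel and
  its 7/19/27-neighbourhood (default 27), midranks with the standard
  tie correction, restricted to in-mask neighbours; under the null the
  interior mean is ≈ 1/27, and W is invariant to per-voxel positive
  affine intensity changes.
- **fALFF**: amplitude (root-power) spectrum of the demeaned series;
  ALFF is the amplitude sum in the band (default 0.01–0.1 Hz,
  inclusive bounds), fALFF divides by the amplitude sum over all
  positive frequencies, so it lies in [0, 1]. The amplitude (not
  squared-power) convention is fixed and tested; the ratio differs
  between conventions, so only one is supported.

## Group statistics

The group model at each voxel is the two-level summary-statistics
model `y_i ~ N(x_i' beta, s_i^2 + sigma_b^2)`, with first-level
variances `s_i^2` carried in from the feature stage. `sigma_b^2 >= 0`
is estimated by a bounded scalar search (upper bound 10x the sample
variance, tolerance 1e-10) on the marginal posterior with the
regression coefficients integrated out under a flat prior — the
restricted-likelihood form, which is what the FLAME stage-1 fast
approximation maximizes. With all within-variances zero and an
intercept-only design this reduces to the sample mean and the (n−1)
sample variance. We deliberately did not use the profiled (plain ML)
likelihood: its 1/n variance convention measurably inflates the null
false-positive rate at n = 30 (≈5.4% mean across simulation seeds,
worst ≈6.8%, versus ≈5.0% for the integrated form at |z| > 1.96).
`beta` is then solved by weighted least squares at the optimum,
contrast variance is `c'(X'V^-1X)^-1 c`, and the t-value with
dof = n − rank(X) is mapped to z by matching tail probabilities (log
tail probabilities, so large z survive).

**Voxel-wise missingness.** Brain coverage differs across subjects, so
a reduced design is built per voxel from exactly the subjects with a
value there (listwise deletion, valid under missing-completely-at-
random). The central correctness property — each voxel's result equals
an explicit fit on the reduced inputs — is asserted at 1e-8 across
hundreds of random voxels. Voxels with fewer than p + 1 subjects are
reported missing, never raised.

**Designs and contrasts.** Flexible factorial designs come from a
small formula language (`group + age + group:age`): categorical main
effects are crossed into cell-indicator columns (cell-means coding, no
separate intercept), continuous covariates are demeaned,
factor-by-continuous interactions multiply indicators by the demeaned
covariate. Missing covariate cells: listwise deletion, or
mean-substitution (zero after demeaning, equivalent to imputing the
observed-sample mean). Categorical-by-categorical interactions are
expressed through the crossed cells themselves; a separate interaction
term would be redundant and is rejected. Pairwise group contrasts
follow the least-squares-means convention: differences of cell means
at the covariate mean (weight 0 on demeaned covariates) with balanced
weights over other factors' cells. Motion-based exclusion uses strict
inequality ("maximum allowed" includes the maximum). FDR correction is
Benjamini–Hochberg over in-coverage voxels of the z-map.

## Quality control

Framewise displacement uses the Power convention (sum of absolute
backward differences; rotations converted to arc length on a 50 mm
sphere). DVARS is unstandardized: the RMS over in-mask voxels of the
backward temporal difference, in raw intensity units. tSNR is temporal
mean over sample standard deviation (ddof 1); the scalar summary
averages over a supplied tissue mask (no segmentation is performed
here). The noise-component fraction is the percentage of ICA
components labelled noise. Visual ratings (good > uncertain > bad)
merge by lattice meet — lower rating wins — which makes the merge
associative, commutative, and idempotent regardless of how many rater
files contribute; a bad anatomical-class rating excludes the whole
subject, a bad functional-class rating only that scan. The
anatomical/functional class is an explicit field on each rating, not
inferred from report names.

## Multiverse planning

Each processing step is identified by a content hash: a SHA-256 digest
of a canonical, sorted, type-tagged JSON serialization of (operation,
parameters, upstream hashes), truncated to four base-26 letters.
Floats serialize via shortest round-trip repr for cross-platform
stability. The full digest is kept per code, so a truncated-code
collision between different steps is detected and resolved by
extending the code — never silently merged (the collision path is
exercised by a brute-force fixture in the tests). Plans are merged by
hash lookup, so shared pipeline prefixes appear once; executing the
deduplicated DAG topologically reproduces the outputs of independent
execution exactly, and each shared node body runs once. Hashing covers
step *specifications*, not file contents. Steps whose required inputs
are absent are pruned with a logged reason instead of failing.

## Synthetic data

The generators produce every input the other modules consume, with
ground truth serialized beside the outputs, and are pure functions of
(parameters, seed). BOLD images are built as baseline + smooth
Gaussian-bump network maps times latent time courses + drift (linear
trend and slow cosines, so both filter families have work to do) +
white noise, inside an ellipsoidal brain mask; default grid 16x16x12
at 3 mm, 120 volumes, TR 2 s — large enough for spectral tests, small
enough for seconds-scale tests. The drift regressors double as
labelled noise components and confound columns; synthetic motion
parameters are random walks. Group data are drawn from the exact
two-level model the group stage assumes, with uniform within-subject
variances (default range 0.2–1.0 against a between-subject variance of
1) and independent voxel-wise MCAR coverage knockout.

What passing tests show — and do not. The generators match the models'
assumptions by construction: Gaussian noise, linear mixing, genuinely
MCAR missingness, white first-level noise. Real data violate all of
these (autocorrelated noise, non-Gaussian artifacts, coverage loss
that tracks anatomy, site effects), so the tests demonstrate
*implementation correctness and calibration under the stated model*,
not robustness to model misspecification. No MR physics is simulated.

## Degenerate inputs and tie-breaking

Masks with ≤1 voxel, constant images, constant seeds, rank-deficient
designs/mixing matrices, and cutoffs outside (0, Nyquist] are errors.
Two path templates matching the same file are refused rather than
tie-broken. Field-map-to-scan assignment beyond shared-tag pairing
(e.g. "nearest preceding scan" heuristics) is not implemented; only
same-tag pairing is provided, and unpaired entries are returned
explicitly rather than dropped. Sanitization collisions in output
naming (two subjects differing only by punctuation) are a hard error.
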