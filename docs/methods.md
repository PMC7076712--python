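# Methods

`patvis` implements an in-line UV-Vis quantification method for an API
dispersed in a polymer melt during hot-melt extrusion (HME), of the kind
used as a process analytical technology (PAT) for real-time content
monitoring: the worked system is piroxicam (PRX, a yellow drug with a
visible absorption band) in Kollidon VA64 (copovidone, KOL). This note
records the models, the tunable parameters with their defaults, the
numerical choices, and what the synthetic data generator does and does
not emulate.

## Measurement model

The instrument records transmittance spectra T(λ, t) through the melt in
the extruder die, 230–816 nm at 1 nm resolution, 0.5 Hz (each stored
spectrum a 10-scan average). Concentration information enters through
Beer–Lambert absorbance after referencing:

1. **Normalisation.** Each sample spectrum is divided by the mean
   steady-state spectrum of a pure-polymer run from the same experiment
   day. Any multiplicative day factor g_day (re-referencing, probe-gap
   changes) cancels identically in the ratio; in absorbance the ratio is
   a baseline subtraction, A_norm = A_sample − A_reference, which the
   test suite checks to 1e−10.
2. **Absorbance.** A = −log10(T). Transmittance values in (0, 1e−6) are
   floored at 1e−6 with a logged count; values ≤ 0 are an error — the
   transform has no continuation there and silent clipping would mask
   detector faults.

## Colorimetry

CIELAB coordinates are computed from the visible range (380–780 nm) by
the discrete tristimulus sums X = k Σ T S x̄ Δλ (likewise Y, Z) with
k = 100 / Σ S ȳ Δλ, so the perfect transmitter has Y = 100 exactly and
rescaling the illuminant cancels. L*, a*, b* use the standard CIE
piecewise function (cube root above (6/29)³, linear below), so black maps
to L* = 0; a plain cube-root variant is available behind
`convention="cube_root"` for literal reproduction of the shorthand
formulas, under which black maps to L* = −16.

The packaged tables are the CIE 1931 2° colour-matching functions
evaluated from the published multi-lobe Gaussian analytic fit (Wyman,
Sloan & Shirley, JCGT 2013) at 5 nm from 380 to 780 nm, with a
daylight-like illuminant (6504 K Planckian radiator normalised to 100 at
560 nm); an equal-energy illuminant is available. Absolute L*a*b* values
depend on the observer/illuminant pair, which in-line instruments do not
generally disclose — the pipeline therefore relies only on ordering and
linearity of the colour response (b* increasing with the content of a
blue-absorbing API), which hold for any non-degenerate tables. 1 nm
spectra are bin-averaged into the 5 nm table grid, preserving the
discrete-sum structure; non-nesting grids are linearly interpolated.

## Steady-state detection

After a feed change the melt composition relaxes roughly first-order to
the new level; spectra from the transition bias any calibration. The
monitor signal is the b* trace (or the first principal-component score of
the absorbance matrix for APIs without a visible band; PC1 sign is fixed
so its largest-magnitude loading is positive). A sample is in-plateau
when two criteria hold, and the selector returns the last run of at least
`min_run` consecutive in-plateau samples (or an explicit no-steady-state
outcome):

* **slope** — the rolling OLS slope of the window centred on the sample,
  normalised by the signal's 5–95 percentile range, is ≤ `rel_slope_tol`
  (default 0.003). Centre attribution makes the onset track where the
  local derivative falls within tolerance: for s(t) = 1 − exp(−t/τ) with
  a tolerance equivalent to |s − 1| < 1%, the detected onset lands at
  τ·ln 100 within a couple of samples, which the suite asserts.
* **detrended SD** — the SD about the window's own least-squares line,
  for the *best* (smallest-SD) window containing the sample, is ≤
  max(`rel_sd_tol`·range, `sd_noise_factor`·noise floor), defaults 0.01
  and 2.5. Raw SD would penalise smooth ramps the slope criterion
  already handles; best-containing-window attribution stops washout
  curvature from smearing half a window into the plateau; and the noise
  floor (median rolling SD over the run) is necessary because the
  rolling SD of a true plateau *equals* the detector noise and can never
  fall below it.

Defaults: `window_len` 60 samples (120 s at 0.5 Hz), `min_run` 30
(60 s). The window length is set by a noise analysis: with transmittance
noise 0.002 the b* trace carries ≈ 0.028 noise SD, and the smallest
level-to-level b* change in the study design (≈ 1.3 units, 5–95 range)
needs ≈ 60 samples before the slope estimator's standard error sits ≥ 4σ
below the threshold. A 20-sample window, the more obvious choice, cannot
separate late washout from plateau at that signal-to-noise. Runs whose
whole 5–95 excursion is within 5× the noise floor are classed trendless
and kept entirely (nothing is washing out).

Against the generator's ground-truth labels (steady when the scheduled
concentration is within 0.5% of target) the default detector agrees at
≥ 95% of samples over a default calibration campaign; disagreement is
concentrated in a short late-transition band where the two definitions
legitimately differ.

## Wavelength selection and calibration

The informative band is the longest contiguous run of wavelengths whose
|PC1 loading| (PCA of the pooled, normalised calibration absorbance
matrix) is at least `threshold_fraction` (default 0.1) of the maximum.
On the study-like synthetic campaigns this selects ≈ 437–543 nm around
the 490 nm absorber, matching the instrument's useful 446–540 nm window,
which is also the default when selection is bypassed (`--band 446:540`).
PC1 explained variance on the selected band is never below its full-grid
value on such data (asserted as a property; the study's specific
percentages are data-dependent).

Calibration is PLS1 via NIPALS deflation (tolerance 1e−10, ≤ 500
iterations per component — for a single response the inner loop converges
immediately) on mean-centred data, y in % w/w unscaled. The composite
regression vector b = W(PᵀW)⁻¹q makes prediction a dot product plus
centring; it equals the minimum-norm least-squares solution at full rank
(≤ 1e−6, asserted against a pseudoinverse oracle and scikit-learn's PLS
in the test suite, where scikit-learn is a cross-check only).

The latent-variable count is chosen by seeded holdout cross-validation:
a stratified 20% split, models with 1..`max_lv` (default 10) components,
and the smallest count whose RMSECV is within 5% of the minimum — an
operational version of the usual elbow read, which a visual rule cannot
reproduce deterministically. An optional repeated-split mode (median
RMSECV over n splits) removes single-split seed fragility. On synthetic
campaigns, whose chemistry is a single absorber, selection selects 1 LV;
a four-effect synthetic system is used to verify that selection finds 4
when four latent dimensions are genuinely needed.

## Validation: accuracy profile

The design is balanced, p series (days) × n replicates per level (the
study: p = 2, n = 50 at 11.66, 13.45, 15.45, 17.50 % w/w). Per level:

* variance components by one-way random-effects method of moments:
  s²_r = MS_within, s²_B = max(0, (MS_between − MS_within)/n),
  s²_IP = s²_r + s²_B (negative moment estimates clipped with a log
  note, so s²_IP ≥ s²_r always);
* relative bias 100(ȳ − y_true)/y_true and recovery = 100 + bias;
* RSDs referenced to the mean predicted concentration (the
  reconciliation of the published uncertainty budget works to printed
  precision under either reference; mean-predicted is used and
  documented);
* the β-expectation tolerance interval in the Mee form,
  bias ± t_{ν,(1+β)/2} · sqrt(1 + 1/(p n B²)) · s_IP with
  R = s²_B/s²_r, B² = (R+1)/(nR+1) and Satterthwaite
  ν = (R+1)² / [(R+1/n)²/(p−1) + (1−1/n)/(pn)]; R = ∞ is handled by its
  limit (B² → 1/n, ν → p−1) and a zero-variance level degenerates to
  [bias, bias]. Since printed summaries round away the information
  needed to reproduce specific published limits, the interval is
  validated by simulation: Monte-Carlo coverage of a future observation
  is 0.95 ± 0.02 for p ∈ {2, 3} under the two-level normal model
  (asserted in the suite). With p = 2 the between-day variance has one
  degree of freedom, so the interval is heavy-tailed — occasional wide
  intervals at small p are a property of the statistics, not a defect;
* total error |bias| + s_IP (absolute and relative) and the uncertainty
  budget u²_bias = s²_B/p + s²_r/(pn), u²_Y = u²_bias + s²_IP,
  U_Y = k·u_Y with coverage factor k = 2.

The method passes when every level's tolerance interval lies inside the
acceptance band ±λ (default 5%); the limit of quantitation is the lowest
passing level. The analytical target profile additionally caps |mean
bias| at 2.0% and both RSDs at 1.8%. Reported values are rounded
half-away-from-zero to 2 decimals; computation is full precision.

## Robustness and MODR

Each robustness DoE run (feed rate × screw speed at nominal content) is
flagged when its |relative bias| exceeds the ATP's 2%. A full quadratic
with interaction, ŷ(f, s) = β0 + β1 f + β2 s + β3 f² + β4 s² + β5 f s, is
fitted to mean predicted content by OLS (statsmodels); the six-term form
is the standard contour-profiler default and is exact on noiseless
quadratic data. The method operable design region is the dense-grid set
(0.05 g/min × 1 rpm by default) where the surface prediction stays
inside the content limits (default 14.15–14.75 % w/w, i.e. the nominal
14.45 ± 2% rounded as published), reported as a grid plus a per-feed-rate
corner table of screw-speed bounds. Widening the limits never shrinks
the region (asserted).

## Synthetic data generator

The generator exists because raw in-line spectra of this kind are not
publicly deposited; its defaults are the study conditions, and every run
carries ground truth (scheduled concentration, injected effective
concentration, steady labels, day gain).

* **Chemistry:** one Gaussian absorber band, centre 490 nm, SD 25 nm,
  absorptivity 1/15 AU per % w/w at centre (peak A ≈ 1 at 15 % w/w);
  polymer baseline a smooth logistic transmittance rising to 0.95 across
  the visible. Absorbance is exactly linear in concentration.
* **Dynamics:** first-order washout between levels, τ = 20 samples;
  steady labels at |c − target| < 0.5% of target. While composition is
  changing, a broad baseline tilt proportional to the remaining washout
  fraction (peak 0.02 AU) emulates melt inhomogeneity — the off-axis
  spectral variance that makes steady-state filtering improve PC1
  explained variance, as observed on real campaigns.
* **Noise:** additive transmittance noise SD 0.002 (detector noise is
  signal-domain); per-day multiplicative gain, lognormal σ = 0.02;
  calibration runs carry 0.6% RSD concentration-equivalent per-sample
  scatter (melt inhomogeneity). With these defaults a default
  calibration campaign (5 levels × 120 steady spectra) yields
  R²_c ≈ 0.999 and RMSEC ≈ 0.09 % w/w — the magnitudes in-line UV-Vis
  achieves in practice. With detector noise alone RMSEC would be
  ≈ 0.01 % w/w, an unrealistically clean instrument.
* **Validation campaigns:** 2 days × 4 levels × 50 replicates; one day
  shift per day, N(0, 0.6%), common to all levels of that day (a day
  effect is instrument state, so it is shared within a day — the
  per-level marginal between-day component is (0.6%·level)² either
  way); per-sample replicate shifts N(0, 0.6%); an optional constant
  injected bias. All shifts are concentration-equivalent, so the
  variance components the profile estimates are known by construction.
* **DoE:** the 3 × 3 + centre-duplicate design at 14.45 % w/w, with the
  systematic (f, s) bias surface supplied by the caller.

What the generator does **not** emulate: real absorber band shapes and
band overlap with polymer absorption, wavelength-dependent day effects
(only the exactly-cancelling multiplicative kind), drift within a day,
probe fouling, bubbles/particulates, thermal degradation, and
residence-time-distribution physics (washout is a single exponential).
Passing tests therefore demonstrate the pipeline's correctness and its
statistical behaviour under a faithful-but-idealised signal model, not
instrument-grade performance on real melts.

## Problem sizes and determinism

Default campaign sizes match the study design (600 calibration spectra,
400 validation predictions per campaign); run lengths are sized so each
level run holds its target steady-sample count plus a 60-sample margin,
and the pipeline keeps the trailing 120 (calibration) / 50 (validation)
detected-steady samples per run, giving exactly the design counts. The
accuracy-profile acceptance quantity is the median over 21 seeded
campaigns of the worst-case |tolerance limit|. All randomness flows from
explicit seeds; campaigns, model fits and reports are bit-reproducible
given the seed, and every report embeds the resolved configuration and
package version.
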