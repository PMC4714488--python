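# Methods

## Scope

`fermiperf` quantifies myocardial perfusion from first-pass
contrast-enhanced CMR at the resolution of the acquired images, segments
overt fibrosis on late gadolinium enhancement (LGE) images, and measures how
much of the apparent ischemic burden is attributable to scar rather than to
microvascular disease.  It is aimed at hypertrophic-cardiomyopathy-style
analyses where fibrosis and microvascular ischemia coexist and confound each
other, but nothing in the implementation is disease-specific.

## Kinetic model

The tissue impulse response is constrained to the Fermi function

    h(t) = R · [1 / (exp((t − τ₀ − τ_d)·k) + 1)] · u(t − τ_d)

with `R` the contrast-influx amplitude, `k` (1/s) the washout decay rate,
`τ₀` (s) the shoulder width during which little contrast leaves the region,
`τ_d` (s) the arrival delay between the LV blood pool and the tissue, and
`u` the unit step.  The measured enhancement curve is modelled as the causal
convolution of the arterial input function (AIF) with `h`, discretised by a
rectangle rule with step `dt` (one sample per heartbeat):

    model(tᵢ) = dt · Σ_{j≤i} aif(tⱼ) · h(tᵢ − tⱼ)

Myocardial blood flow is the initial height of the impulse response.  A
literal `h(0)` is zero whenever `τ_d > 0` because of the unit step, so MBF
is evaluated with the delay removed:

    MBF = R / (exp(−τ₀·k) + 1)

This choice (rather than, e.g., `h(τ_d)` which is numerically identical, or
a literal `h(0)` which would be degenerate) is the only self-consistent
reading of "MBF = h at t = 0" for a delayed response.  Units are nominal
mL/g/min under the linear signal–concentration assumption that the
dual-bolus protocol exists to justify; every accuracy statement made by the
test suite is relative, not absolute.

Myocardial perfusion reserve (MPR) is the pixelwise (or segmental) ratio of
stress to rest MBF, valid only where both fits are valid and rest MBF is
strictly positive.

## Fitting

`(R, k, τ₀)` are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with `τ_d` held
fixed.  A Levenberg–Marquardt iteration would be the classical choice for
this problem, but it cannot enforce the parameter bounds below; the
objective and solution are the same.

* Bounds: `R ∈ (0, 100]`, `k ∈ [10⁻⁴, 10]`, `τ₀ ∈ [0, 60]`.
* Initialisation: `R₀ = peak(tissue) / peak(∫aif dt)`, `k₀ = 0.1 s⁻¹`,
  `τ₀,₀ = 5 s`, clipped into the bounds.
* Termination: `ftol = xtol = 10⁻¹²`, at most 2000 objective evaluations.
  The tight tolerance costs little (curves have ~40–60 samples) and makes
  noiseless round-trips exact to solver precision.
* Degenerate inputs (all-zero tissue curve, non-convergence) yield an
  invalid result with `MBF = NaN`; pixel maps record them in a validity
  mask and never interpolate.

`τ_d` is chosen per curve (or once per slice from the mean myocardial
curve, which is how the pixelwise mapper uses it) by exhaustive search over
integer-frame candidates 0..5, keeping the delay whose trial fit has the
smallest residual; ties resolve to the smallest delay.  Baseline signal is
removed by subtracting the mean of the first 3 pre-contrast frames
(configurable).

The dual-bolus convention is implemented by multiplying the measured
low-dose AIF by `dose_ratio` before deconvolution; the ratio is a free
configuration parameter (default 10, the usual 1:10 pre-bolus).

## Preprocessing

* **Coil-bias correction** divides each frame by the proton-density-derived
  sensitivity field, normalised to unit mean over the myocardium, making the
  correction invariant to the field's global scale.
* **Motion correction** is translation-only.  Each frame is registered to
  its temporal neighbour by maximising normalised cross-correlation over an
  automatically determined heart ROI (Otsu threshold on the temporal
  maximum-intensity projection, holes filled so the blood pool stays
  inside, dilated 3 px), and the per-step shifts are accumulated outward
  from the frame of peak mean signal.  Neighbour-to-neighbour registration
  is essential: frames before myocardial enhancement share almost no
  contrast with a late reference frame (their only feature, the blood pool,
  is comparatively dark there), so direct registration to a single
  reference is ill-posed exactly where motion correction matters.  Integer
  shifts are applied by circular rolling, which preserves frame histograms
  exactly; zero-variance frames are flagged and passed through, their
  displacement being unobservable.
* **Temporal MIP** (pixelwise max over time) is the feature image for
  contouring.  Automatic contour delineation is deliberately not provided
  beyond this; contours are operator (or phantom) input.

## Scar segmentation and transfer

Overt scar is defined as myocardial signal strictly greater than
`mean + n_sd·SD` of an operator-chosen remote, non-enhanced region, with
`n_sd = 6` by default.  Strict inequality is used because a pixel exactly
at the threshold is not "above" it; with continuous-valued images the
choice is immaterial in practice.  No minimum-component filtering is
applied by default (a `min_size` post-filter exists, off by default).  The
remote region is an input, not auto-detected — the choice is an operator
degree of freedom, and the interobserver analysis exercises it explicitly.

LGE and perfusion slices are acquired in different cardiac phases, so the
scar mask must be transferred between contour geometries.  Instead of a
deformable registration, each myocardial pixel is described by two
contour-normalised coordinates — counter-clockwise angle from the
RV-insertion reference, and transmural depth fraction between the endo- and
epicardial contours — which are preserved across geometries.  The transfer
pulls: every perfusion myocardial pixel looks up its (angle, depth) twin in
LGE space and takes the nearest pixel's label.  This is deterministic,
exactly the identity for identical contours, a subset of the target
myocardium by construction, and testable on analytic annuli (angle
preserved to <1°, area fraction to <2% on a 1.2× scaled annulus at
128×128).  It assumes star-shaped contours about the endocardial centroid,
which holds for short-axis LV geometry.

## Ischemic burden

Burden at threshold θ is the percentage of evaluable myocardium with
MPR < θ, pooled over all slices.  For segmental results each segment
contributes its full pixel count at its segmental MPR.  Scar correction
removes overt-scar pixels from numerator **and** denominator, i.e. the
corrected burden is the ischemic percentage of non-scarred myocardium;
removing them from the numerator only would understate burden in heavily
scarred ventricles.  Invalid pixels are excluded from both counts.  The
default threshold grid is 0.5–2.5 in steps of 0.1.

The relative error `100·(uncorrected − corrected)/uncorrected` is flagged
undefined (NaN) where the uncorrected burden is zero.

Tertiles of per-subject burden are equal-count splits of the uncorrected
values; corrected values are re-scored against the same boundaries.  Ties
are ordered by stable subject position both when forming boundaries and
when re-scoring, so an unchanged cohort is never recategorised; re-scoring
never moves a subject up.  Interobserver reproducibility of the corrected
burden uses Bland–Altman bias and 1.96·SD limits (sample SD, ddof = 1) plus
Pearson correlation, flagged undefined for zero-variance inputs.

## The phantom

The synthetic-data module defines the conditions under which everything is
tested; its defaults are fixed, not tuned.

* **Geometry**: three short-axis slices (basal, mid, apical) on a 64×64
  grid at 1.2 mm spacing, concentric circular contours (endo/epi radii
  18/27, 16/25, 12/19 mm), one frame per heartbeat (`dt = 1 s`), 60 frames.
  Basal and mid slices carry 6 angular segments each, apical 4 — the 16
  standard segments, the apical cap being outside a 3-slice acquisition.
* **AIF**: gamma-variate `A·((t−t₀)/β)^α·exp(−(t−t₀)/β)` with `A = 1`,
  `t₀ = 4 s`, `α = 2`, `β = 3 s` — a compact first-pass bolus peaking at
  `t₀+αβ = 10 s`.  The generated curve is the low-dose pre-bolus; tissue
  sees `dose_ratio`× that input.
* **Tissue**: every myocardial pixel's course is baseline (10) plus the
  convolution of the full-dose AIF with a Fermi response whose delay-free
  initial height equals that pixel's true MBF.  All pixels share
  `k = 0.3 s⁻¹`, `τ₀ = 5 s`, `τ_d = 2 s`, varying only in amplitude, so
  the ground truth is unambiguous.  Default true MBF: 1.0 at rest,
  3.0 at stress; defect and scar regions override the stress value.
* **Noise**: zero-mean Gaussian on magnitude, either as an explicit σ or
  via a target SNR defined as peak mean myocardial enhancement over σ.
  Rician noise is deliberately not simulated: at first-pass myocardial SNR
  the Gaussian approximation is adequate and keeps recovery statements
  verifiable.
* **Motion/coil artifacts**: optional integer translation jitter per frame
  (circular roll) and a smooth multiplicative bias field; nothing else
  (no k-t undersampling artifacts, no dark-rim simulation — dark-rim
  handling is an optional operator-supplied exclusion mask).
* **LGE**: remote myocardium `Normal(100, 10)`; scar pixel means elevated
  by `offset·SD` with offset 10 by default (comfortably above the 6-SD
  rule); the remote reference ROI is a sector diametrically opposite the
  scar.  Cohort scars additionally carry an epicardial rim at 6.5 SD so
  the segmented extent depends slightly on the observer's remote choice,
  giving the reproducibility analysis something real to measure.
* **Cohort**: `round(prevalence·n)` subjects (default prevalence 0.7,
  mirroring the ~70 % LGE-positive rate typical of such cohorts) get scar
  with scar MPR drawn in 0.5–0.9 and a moderately hypoperfused peri-scar
  band (MPR 1.3); scar-positive subjects are also more likely (0.8 vs 0.5)
  to carry an LGE-negative subendocardial defect (MPR 1.2–1.5), so they
  keep a larger burden even after correction.  Resting MBF varies
  N(1.0, 0.1), hyperemic response N(3.0, 0.35).  All generators are pure
  functions of (spec, seed).

A dedicated deterministic phantom (`correction_analysis_spec`) expresses
the scar-correction regime analytically: scar apparent MPR follows a
triangular density on [0.5, 1.4] (convex CDF), a small fraction of
non-scar pixels is uniform on the same interval, and the rest sits above
the threshold grid.  Under these populations the scar MPR distribution
stochastically dominates the non-scar one from below, so corrected burden
provably never exceeds uncorrected, and the relative-error curve is
provably non-decreasing up to the scar ceiling and exactly flat beyond —
the shape the correction analysis is designed to exhibit.  The identity
`err = 1 − (N/(N−S))·n(θ)/(S(θ)+n(θ))` makes both properties checkable by
hand.

### What the phantom does not capture

Real data add: signal saturation and T1-dependence breaking strict
linearity, Rician noise at low SNR, dark-rim and k-t reconstruction
artifacts, through-plane motion, imperfect contours, genuinely deformable
LGE↔perfusion misalignment, and physiologic heterogeneity of the kinetic
shape parameters.  Passing tests therefore demonstrate that the estimator
chain is correct and self-consistent under its stated model, not that
clinical accuracy claims transfer to scanner data.

## Problem sizes

Pixelwise fitting costs ~5 ms per pixel, so the suite scales simulations to
what the checks need: single-slice 64×64/60-frame phantoms for recovery
checks (~850 myocardial pixels), 200 replicates per condition for noisy
recovery, 50 seeds for scar Dice, and a 30-subject cohort on a 48×48 grid
(1.8 mm spacing, 40 frames) for the full-pipeline cohort statistics; the
cohort's tertile check uses truth-derived MPR maps, which exercises the
burden/tertile machinery without 50k redundant fits.

## Known limitations

* The Fermi fit is mildly degenerate in (R, k, τ₀) under heavy noise; MBF
  is well-identified but individual shape parameters should not be
  over-interpreted.
* Translation-only motion correction cannot represent rotation or
  deformation; it matches the phantom's motion model by design.
* Segmental analysis uses transmural averages; endo/epi layer analysis is
  not implemented.
* LGE extent is pixel-area over all slices, not mass-weighted.
* Whole-LV burden pools pixels across slices rather than averaging
  per-slice burdens; with three equal-weight slices the difference is the
  slice-size weighting.
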