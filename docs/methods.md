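# Methods

## The simulated study

Each run emulates one dynamic brain CT-perfusion acquisition at low dose
and asks whether sinogram-domain restoration improves the perfusion maps
a clinician would read. Three arms share one noisy dataset per seed: the
noiseless **clean reference** (always computed; it defines "correct"),
the **unrestored** arm (noisy sinograms reconstructed directly), and the
**restored** arm (PWLS + adaptive weighting before reconstruction).
Metrics compare each arm's maps with the clean reference over the brain
mask, so that FBP discretization error — common to all arms — cancels and
only the noise response is scored.

## Phantom

A 2-D head phantom composed of ellipses: a brain ellipse of normal
tissue, an ischemic penumbra in one hemisphere, an infarct core inside
it, and a small feeding artery. Regions are painted in that order (later
regions overwrite earlier ones). Every pixel of a class follows the same
peak-normalized gamma-variate time-attenuation curve

    c(t) = baseline + A·u^α·exp(α(1 − u)),   u = (t − d)/(αβ),  t > d,

which equals `baseline` exactly up to the arrival delay d and reaches its
maximum `baseline + A` exactly at t = d + αβ. This parameterization makes
the ground truth analytic: TTP = d + αβ; the enhancement AUC over the
scan window has a closed form in the lower incomplete gamma function; the
maximum upslope of the rising limb is attained at u* = 1 − 1/√α for
α > 1. Default kinetics (HU-like units):

| class     | baseline | amplitude A | delay d (s) | α | β (s) | TTP (s) |
|-----------|---------:|------------:|------------:|---|------:|--------:|
| artery    | 45       | 200         | 2.25        | 3 | 1.0   | 5.25    |
| normal    | 40       | 30          | 4.5         | 2 | 2.0   | 8.5     |
| penumbra  | 38       | 15          | 6.75        | 2 | 3.0   | 12.75   |
| core      | 35       | 5           | 9.0         | 2 | 4.0   | 17.0    |
| background | −1000   | 0           | —           | — | —     | —       |

Enhancement amplitude decreases and arrival is delayed from normal tissue
through penumbra to core — the hypoperfusion gradient that makes the
lesion visible on perfusion maps. The time grid is 20 frames at 2.25 s
(45 s scan). Units are Hounsfield-like; absolute iodine calibration is
out of scope.

What the phantom does **not** emulate: anatomy (vasculature, ventricles,
skull), partial-volume and beam-hardening effects, patient motion, bolus
dispersion and recirculation, 3-D geometry. Passing tests therefore show
that the restoration chain behaves correctly under its stated noise
model, not that it is clinically validated.

## Projection and noise

Parallel-beam geometry, 180 views over [0°, 180°), ray discretization by
scikit-image's Radon transform. Frames are converted from HU to linear
attenuation (μ = 0.19·(1 + HU/1000) cm⁻¹, so air vanishes) and line
integrals are scaled by the pixel size (18 cm field of view), putting
head path lengths at ā ≈ 2–3. Noise is injected in the line-integral
domain as zero-mean Gaussian with the mean–variance law

    σᵢ² = (1/P₀)·exp(āᵢ)·[1 + (1/P₀)·exp(āᵢ)·(σₑ² − 1.25)],

evaluated at the clean value āᵢ (the noise-free truth is available in
simulation); negative noisy line integrals are clipped to zero. Defaults
P₀ = 5·10⁴ and σₑ² = 10 give ~3000 detected counts along central rays —
a genuinely low-dose regime with ~1% relative projection noise. The
variance map is kept and reused as the PWLS weighting and the adaptive
threshold; the same model would apply to measured data via a plug-in
estimate of ā. The bracket can only go negative at parameter extremes
never reached by the pipeline; a small positive floor plus a logged
warning guards that case.

## Restoration

The objective is written with the conventional ½ on both quadratic
forms,

    Φ(p) = ½ Σ (y − p)²/σ² + (β/2) Σ (p − med(p[N]))²,

because that is the objective whose lagged-median coordinate minimizer is
exactly the Gauss–Seidel update (y + βσ²·med)/(1 + βσ²); scaling
conventions only re-parameterize β. Design points:

* **Diagonal weighting.** The per-ray closed-form update is only
  consistent with a diagonal covariance; off-diagonal ray correlations
  are not modeled.
* **Lagged median.** The penalty is nonsmooth through the median; the
  update treats it as a constant at the current iterate. Monotone descent
  of Φ is therefore not claimed — the objective trace is recorded, but
  the stopping rule is iterate convergence: max absolute update below
  `tol` (default 10⁻⁶) times the sinogram dynamic range, capped at 200
  sweeps. In practice the default pipeline converges in ~10 sweeps.
* **Edge handling.** Neighborhoods shrink at sinogram edges (3 neighbors
  at edges, 2 at corners; even counts take the mean of the middle pair).
  No padding or wraparound, so no data are invented.
* **Sweep order.** Raster (view-major) by default; reverse-raster is
  available and converges to the same objective within a fraction of a
  percent, never bit-identically.
* **Range preservation.** Each update is a convex combination of the
  datum and a median of current values, so the restored sinogram stays
  inside the data range — restoration cannot manufacture out-of-range
  line integrals.
* **β default 6000.** β·σᵢ² ≈ 1–2 on typical low-dose rays, i.e. roughly
  equal weight on the datum and its neighborhood median at the fixed
  point. The value was fixed once by a pilot sweep of the downstream
  perfusion-map PSNR gain at the default study conditions and checked for
  stability across disjoint seed sets. Because σᵢ² enters the update
  per-ray, smoothing is automatically stronger exactly where the dose is
  lowest.
* **λ default: 75th percentile** of the variance map, replacing the
  noisiest quarter of rays with restored values and leaving quiet rays
  untouched. An absolute-threshold mode exists for externally supplied
  variances.

The sweep itself is a numba-compiled kernel: the updates are strictly
sequential (each one must see already-updated neighbors), which rules out
a vectorized formulation.

## Reconstruction and perfusion maps

Standard filtered back-projection (ramp filter by default, Hann and
Shepp–Logan apodization available) via scikit-image, with the pixel-size
scale divided out and an inscribed-circle mask. Tolerances in tests are
relative to image dynamic range to stay backend-agnostic.

Maps use the simplest well-defined conventions: CBV = 100·AUC(tissue
enhancement)/AUC(AIF enhancement) (trapezoidal over the scan); CBF =
maximum finite-difference upslope of tissue enhancement divided by the
AIF peak; MTT = CBV/CBF (central volume theorem) wherever CBF exceeds 1%
of the map maximum, NaN elsewhere; TTP = time of the enhancement argmax,
ties to the earliest frame. The AIF is the mean curve of the phantom's
artery pixels (or a user mask on external data); the baseline is the mean
of the first 2 frames. Deconvolution-based CBF and delay/dispersion
correction are deliberately out of scope, so absolute CBF/MTT values are
method-specific surrogates; the evaluation compares arms under the *same*
convention, which is what the restoration question requires.

## Metrics

RMSE over the evaluation region; PSNR = 20·log₁₀(max(reference)/RMSE)
with the reference maximum taken over the region; UQI is the Wang–Bovik
index with population (1/n) moments. NaN pixels (invalid MTT) are
excluded pairwise. PSNR of a perfect match is reported as +inf.

## Problem sizes and determinism

The default experiment runs at 64² with 180 views and 20 frames — large
enough that FBP artifacts and noise propagation behave as at clinical
matrix sizes, while a ten-seed sweep of all three arms completes in well
under a minute; the phantom builder itself supports up to 512². All
randomness flows through explicit integer seeds (phantom, noise, batch
sweeps), and a fixed seed reproduces runs bit-identically up to the
floating-point determinism of the underlying libraries.

## Known limitations

* The restoration operates per frame; temporal correlation between
  frames is not exploited.
* The adaptive weighting is a hard threshold, so ỹ is discontinuous in
  σ²; a soft weight would trade the exact limit behavior for smoothness.
* The Gauss–Seidel fixed point depends (weakly) on sweep order because
  the median is lagged inside the sweep.
* MTT inherits the noise of both CBV and CBF and is near-singular where
  CBF is small; its fidelity gain from restoration is accordingly the
  smallest of the four maps.
* DICOM ingestion of clinical CTP series is not implemented.
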