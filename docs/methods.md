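# Methods

This note records the models, parameter choices and numerical conventions
behind `sute-ac`, and what the synthetic phantom does and does not emulate.

## Signal and segmentation model

**UTE signal.** Echoes follow a mono-exponential magnitude decay
`I(TE) = PD · exp(−TE · R2*)` per voxel, with echo times TE₁ = 0.07 ms and
TE₂ = 2.46 ms. The R2\* map is the two-point log-ratio
`R2* = (ln I₁ − ln I₂)/(TE₂ − TE₁)` (1/ms). The natural logarithm is used;
any other base would only rescale the downstream calibration polynomial,
which is fitted anyway. Intensities are floored at 1e-6 of the global
maximum before the logarithm, and negative rates (noise can make I₂ > I₁)
are clamped to zero.

**Mixture model.** Segmentation is EM on a Gaussian intensity mixture with
spatial priors: the E-step posterior is proportional to
`TPM_k(x) · Σ_j w_kj N(I(x); μ_kj, σ²_kj)`; the M-step uses
posterior-weighted moment updates with the within-class weights
renormalized per class. Only the first echo enters the likelihood — the
second echo is used solely for R2\*. Defaults: one Gaussian per class,
convergence at a relative log-likelihood change below 1e-6 or 100
iterations, variance floor 1e-4 of the global intensity variance (prevents
component collapse). Means and variances initialize from prior-weighted
moments; when priors are uninformative the class means coincide, so the
initializer falls back to evenly spaced intensity quantiles to break the
symmetry. The log-likelihood trace is non-decreasing (EM monotonicity);
with the optional polynomial bias correction (log-domain least squares of a
3rd-order 3-D polynomial against class-predicted intensities, re-estimated
between EM passes) strict monotonicity across refits is not guaranteed, so
the correction defaults to off.

**Hard labels.** Air posterior above 0.1 → air; bone posterior above 0.2 →
bone. The two rules can both fire at a voxel; bone wins by default because
missing skull is the costlier PET error. The precedence is configurable.

## Attenuation coefficients and calibration

Assigned μ at 511 keV (cm⁻¹): air 0, soft tissue 0.100, bone 0.151 (fixed
mode), GM 0.099, WM 0.099, CSF 0.096 (six-class mcAC map). Continuous bone
mode maps R2\* through a degree-3 polynomial constrained non-decreasing
over its fit range and clamped to [0.100, 0.20] cm⁻¹ — bone must not fall
below soft tissue, and 0.20 bounds cortical bone plausibly. The shipped
default calibration interpolates two physical anchors (0 /ms → 0.100,
2.0 /ms → 0.151 cm⁻¹); continuous-mode results are therefore
calibration-dependent and should be read as such.

Assembled maps are smoothed with a 2-mm Gaussian; all kernel widths in the
package are FWHM (neuroimaging convention), σ = FWHM/(2√(2 ln 2)).
Smoothing pads with zeros because the physical background is air (μ = 0).
Order of operations at the field-of-view seam: assign → smooth → paste the
fallback map unsmoothed outside the coverage mask (no blending).

CT conversion uses the standard bilinear model anchored at air
(−1000 HU → 0) and water (0 HU → 0.096 cm⁻¹) with a configurable bone
slope (default 6.4e-5 cm⁻¹/HU above 0 HU); these parameters are this
package's documented choice, not a published fit. CT classification uses
strict thresholds (below −500 HU air, above 300 HU bone); vendor-map
classification matches μ = 0.151/0 cm⁻¹ within ε = 1e-6.

## Template and TPM construction

The template is the arithmetic mean of aligned first-echo images;
registration is pluggable and the phantom workflow supplies known
(identity) transforms — no deformable registration is implemented. Class
masks are averaged (trilinear after alignment), lightly smoothed (3-mm
FWHM) to emulate inter-subject prior softness, then renormalized with air
and bone protected: where the per-voxel sum exceeds 1, protected values are
kept and the remaining classes scale by `(1 − Σ_protected)/Σ_nonprotected`;
the same multiplicative fill applies where the sum falls short, so
probabilities always sum to exactly 1. Voxels with zero total mass become
air (background); voxels with protected mass below 1 but no non-protected
mass put the deficit into soft tissue. Probabilities are resampled first
and renormalized second.

## PET simulator

2-D slice-wise parallel-beam geometry: default 180 angles over 180°, 128
radial bins of 2 mm. The projector is a ray-driven Joseph-method sparse
matrix (linear interpolation at each dominant-axis crossing, step length
spacing/|cos θ| in cm); its exact transpose is the backprojector, so the
matched-pair MLEM properties hold (non-negative iterates, count
conservation, monotone likelihood). Verified accuracy: the closed-form ACF
of a uniform μ = 0.1 cm⁻¹ disc over a 10-cm chord is reproduced within 0.8%
at 128² resolution across angles.

Emission data are Poisson with mean `ACF(μ_true) · P(activity)` rescaled to
a total count budget (default 5×10⁶ per slice set). Reconstruction is OSEM
with the attenuated system model `diag(ACF)·P`, 3 iterations and 21 subsets
(reduced with a warning to the largest divisor of the angle count, 20 for
180 angles), followed by a 5-mm FWHM in-plane Gaussian post-filter. No TOF,
PSF, scatter or randoms are modelled: the simulator isolates the
attenuation-induced bias that the evaluation measures.

## Evaluation conventions

* Dice uses the sum denominator `2|A∩B|/(|A|+|B|)`; the literal
  union-denominator variant (which equals 2 for identical masks) is exposed
  as `dice_as_printed` for audit. Empty-vs-empty Dice is 1, empty-vs-
  nonempty 0.
* FP rate = fraction of predicted-positive voxels that are false; FN rate =
  fraction of reference-positive voxels missed; 0 when the respective
  denominator is empty. All segmentation metrics are computed within the
  head region (skull and interior, including air cavities).
* The relative-error map is `R = 100·(ref − x)/ref` (a reduction in
  activity is positive); tabulated per-method biases are reported with the
  opposite orientation `100·(x − ref)/ref`, and the pipeline report carries
  both (`reduction_pct_ref_minus_x`, `re_pct_x_minus_ref`). Reference
  voxels below 1e-6 of the in-mask mean are excluded (undefined), never
  imputed.
* Representative histograms: 150 bins per subject over the subject's own
  masked range; the subjects×bins matrix is SVD-decomposed and the leading
  right-singular vector (sign-fixed non-negative-dominant, scaled by
  s₀/√n) is the representative curve.
* Mann-Whitney U: exact enumeration of all group assignments with mid-ranks
  for combined n ≤ 16 (two-sided p = 2·min(P(U≤u), P(U≥u)) capped at 1);
  tie-corrected continuity-corrected normal approximation otherwise. No
  multiplicity correction is applied.

## Synthetic phantom

The phantom emulates what the method needs from a real acquisition: nested
head geometry (scalp/face soft tissue, a closed ellipsoidal skull vault,
GM rind, WM core, CSF ventricles, air sinuses in the facial soft tissue), a
region atlas with six named brain regions (frontal, parietal, occipital, a
cerebellum-like inferior region, deep central, periventricular), per-tissue
proton density and R2\* (bone 2.0 /ms; soft tissues ≤ 0.03 /ms — chosen so
the 0.07/2.46 ms echo pair yields the bone-suppression contrast), true μ
values equal to the method's assigned coefficients, and an FDG-like
activity map with GM:WM:CSF = 4:1:0.1. Noise is Rician at 3% of the
soft-tissue first-echo intensity by default; an optional low-order
polynomial bias field is off by default. Everything is deterministic per
seed.

What it does **not** emulate — and hence what passing tests do not show
about real data: partial-volume mixing at tissue borders (class intensities
are cleanly separated, which is why phantom Dice scores saturate near 1
while clinical bone Dice is far lower), k-space/radial UTE acquisition
artifacts, susceptibility and chemical-shift effects, inter-subject
anatomical variability beyond affine-scale jitter, and registration error
(the cohort is generated pre-aligned). PET-side omissions are listed above.

## Problem sizes

The fast profile — used by the test suite and the acceptance script — runs
the full workflow on a 96³ grid at 2-mm isotropic voxels, a five-subject
template cohort, nine reconstructed transaxial slices spanning the
cerebellum-like, periventricular and parietal regions, and 5×10⁶ counts per
slice set; a `full` profile (160³, 1.56 mm) is available via the
configuration. EM correctness is additionally cross-checked against an
independently coded reference EM on 200 random 1-D instances, and the
metric implementations against exhaustive-counting and full-enumeration
oracles.

## Known limitations

* The continuous bone mode inherits the R2\* noise floor: where the second
  echo falls to the noise level, R2\* is underestimated and continuous bone
  μ biases low (visible as a ~−2.5% whole-brain PET bias on the default
  phantom, versus ~0% for the fixed coefficient).
* The bundled calibration is anchor-based, not fitted to measured
  bone data; continuous-mode accuracy is calibration-limited by design.
* The 2-D simulator propagates in-plane attenuation errors only; oblique
  lines of response in a real 3-D acquisition are not modelled.
* No MRF/cleanup spatial regularization is applied after the GMM, and
  deformable registration is out of scope throughout.
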