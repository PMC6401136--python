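# Methods

`holosperm` simulates off-axis digital holographic microscopy (DHM) of
human sperm cells under an oxidative-stress deformation, reconstructs
quantitative phase maps by Fourier sideband filtering, extracts eleven
morphological and texture predictors from the head region, and separates
control from stressed cells with a support vector machine. This note
records the models, the parameters that matter, the conventions the
package fixes where the underlying physics or literature leaves a choice
open, and what the synthetic validation does and does not establish.

## Hologram model

The recorded interferogram is

    h(x, y) = a(x, y) + b(x, y) · cos[2π(f_x x + f_y y) + Δφ(x, y)],

with background `a`, modulation `b` (camera counts), spatial carrier
(f_x, f_y) in cycles/pixel, and object phase Δφ in radians. The default
carrier is (0.125, 0.125): far enough from DC that the object sideband
separates cleanly at the default object bandwidth, and bin-aligned on a
512-pixel grid so the noiseless pattern is exactly periodic.

Two illumination regimes emulate a direct He–Ne laser and a
pseudo-thermal (rotating-diffuser) source:

* **coherent** — the complex fringe envelope is multiplied by a partially
  developed speckle field `u = (1 − C) + C·ζ`, where ζ is a correlated
  circular complex Gaussian field (correlation length 8 px), and a
  parasitic low-frequency fringe is added. Speckle phase propagates into
  the reconstruction and sets the flat-region phase noise.
* **pseudo_thermal** — speckle-free fringes plus i.i.d. Gaussian
  intensity noise (σ_I counts); intensities are clipped at zero as a
  camera would.

The preset values `C = 0.31` and `σ_I = 286` are *calibration presets*:
they were chosen once so that the spatial phase sensitivity of the
default end-to-end pipeline — the standard deviation of the
reconstructed phase over a specimen-free region — lands at ≈300 mrad
(coherent) and ≈20.0 ± 0.2 mrad (pseudo-thermal), the two regimes a
Linnik DHM shows with and without a rotating diffuser. The ordering
(coherent noisier than pseudo-thermal) is asserted per seed in the tests.

## Sperm phantom

A phantom is a nonnegative phase field on a 512 × 512 grid at
0.1 µm/pixel (a pitch consistent with high-NA microscopy sampling; the
µm scale is a package convention — absolute calibrations are not
available from the source data, only shapes and ratios matter):

* **head** — `φ_peak·(1 − (ξ/a)² − (η/b)²)^q` with q = 0.5 (half-ellipsoid
  cap), semi-axes a = 2.25, b = 1.5 µm (a 4.5 × 3 µm head) and
  φ_peak = 4 rad, the peak optical path delay a healthy head produces at
  632.8 nm in reflection;
* **midpiece** — a 4 µm tapered ridge (1.3 rad) with Gaussian
  cross-section;
* **tail** — an undulating ribbon of 45 µm centerline arc length
  (matched numerically to < 0.1 %), 0.45 µm wide, 0.3 rad peak — the
  low-contrast structure that only the pseudo-thermal regime resolves.

Per-cell biological variability is modelled by multiplicative jitter
(CV 5 % on sizes and peak phase, 10 % on midpiece/tail amplitudes),
uniform orientation in 25–55°, ±0.8 µm placement jitter and a random
tail wave phase. All randomness derives from one base seed through
`numpy.random.SeedSequence([base, class, cell])`, so datasets are
bit-reproducible.

## Stress deformation

Hydrogen-peroxide-induced oxidative stress flattens the head at
approximately constant volume. The transform at stress level s ∈ [0, 1]
has three components, all conserving the integrated head phase (the
optical volume):

1. **Flattening** — peak phase scaled by (1 − κs) with κ = 0.115,
   calibrated so s = 1 reproduces the ≈11.5 % drop of the head-phase
   mean observed between control and 10 µM H₂O₂; the semi-axes scale by
   1/√(1 − κs) so the analytic volume is conserved, and a residual
   rescale pins the *discrete* head sum exactly (|ΔV|/V < 10⁻⁶ is a
   tested invariant).
2. **Edge softening** — a Gaussian blur of width 0.5·s µm. Loss of the
   crisp membrane edge spreads a low-phase skirt outward past the
   nominal ellipse and softens the apex.
3. **Chromatin texture** — a correlated zero-mean roughness field
   (std 0.6·s rad before tapering, correlation length 0.5 µm), tapered
   by h(1 − h⁴) of the normalized height so it vanishes at the apex
   (max-phase monotonicity is preserved) and at the rim (the support is
   unchanged and the field stays nonnegative), then orthogonalized
   against the taper so the head integral is unchanged exactly.

Components 2 and 3 were calibrated once, before freezing, against the
qualitative effect the deformation must emulate — maximum phase, ROI
mean, variance and GLCM energy decreasing; surface area, kurtosis,
skewness and histogram entropy increasing; volume approximately
constant; sphericity decreasing — as measured through the *full*
pipeline (the instrument's band limit attenuates fine texture, so
phantom-level effect sizes do not transfer directly). Pure self-similar
scaling provably cannot produce the texture directions: every
standardized moment, the histogram entropy and the GLCM energy are
invariant under an affine rescaling of the field. The direction pattern
therefore requires genuine shape change (blur) and heterogeneity
(roughness), which is also how the underlying biology is described
(membrane softening, chromatin de-condensation).

One consequence is measurable and documented rather than hidden: the
blur skirt carries ~6–8 % of the stressed head's volume beyond the
zero-level ellipse that segmentation recovers, so the *measured* median
volume drifts by that much across the stress range even though the
generator conserves volume to machine precision. The validation asserts
both facts separately (exact conservation at 10⁻⁶; measured drift
< 10 %, an order of magnitude below the +25 % surface-area and −19 %
max-phase effects). A hysteresis "threshold-then-grow" segmentation that
recovers the skirt was evaluated and rejected because it annexes Gibbs
ringing around the head and degrades the head-mask IoU from ≈0.95 to
≈0.7.

**Paired sweeps.** Dose–response experiments reuse the same geometry and
roughness seeds for a given cell index at every stress level and redraw
only the illumination noise. Median trends across levels then measure
the deformation rather than the geometry jitter — the synthetic
analogue of a within-subject design. Classification datasets use
independent cells per class.

## Phase reconstruction

FFT → sideband location (maximum-magnitude bin in the upper half-plane
outside a 0.05 cycles/px DC guard, refined by a 3×3 centroid) → circular
window → inverse FFT with carrier demodulation → four-quadrant arctangent
→ reliability-ordered 2D unwrapping (scikit-image), anchored by the
histogram mode so the background sits at ≈0 while output ≡ input
(mod 2π) pointwise → least-squares polynomial background removal
(total degree 2, fitted on specimen-free pixels, Otsu-estimated when no
mask is given; ≥20 % background required) with the background median
forced to zero. Sign convention: the object is optically thicker than
the surround (positive phase); the upper-half-plane sideband choice
fixes the carrier sign.

The default window is Gaussian with 1/e radius ⅓ of the DC-to-carrier
distance — a soft window suppresses ringing under noise. For *noiseless*
fidelity validation the package reconstructs with a hard window at 0.65
of the carrier distance instead: with a constant background the DC term
is a spectral delta, so a wide window is admissible, and the noiseless
round trip is then resolution-limited at RMSE ≈ 0.012–0.018 rad (the
cap's rim slope of ~1.2 rad/px cannot be followed at the default ⅓
resolution, which saturates the error at ≈0.028 rad regardless of
algorithmic correctness). Fidelity metrics exclude a 16-px border
(filter edge effects). Linearity is validated on the head-mask mean
(doubling every phantom amplitude doubles it within 1 %); the pointwise
maximum is not a valid probe because a low head makes the head–midpiece
junction the global maximum and Gibbs overshoot can exceed the dome.

Optical thickness follows OT = φλ/4π in reflection (the beam traverses
the specimen twice) and φλ/2π in transmission, in nm; refractive index
and geometric thickness are never separated — all downstream quantities
are optical.

## Morphometry

* **Segmentation** — 3×3 median filter, Otsu threshold, opening with a
  radius-2 disk (removes the tail), largest connected component within
  200–20 000 px (ties broken by higher mean phase), then boundary
  recovery: a threshold at level `thr` truncates a cap profile at the
  ellipse scaled by √(1 − (thr/peak)²), so the fitted component ellipse
  is extrapolated back to the zero level. Without this step Otsu
  (≈1.5 rad on a 4-rad head) truncates the rim and the mask-IoU against
  ground truth is 0.82–0.88; with it, 0.92–0.98.
* **Volume** — V = Σ_mask OT·dx·dy, reported in µm²·nm (optical volume;
  no refractive-index conversion exists or is attempted).
* **Surface area** — Monge parameterization on the µm-converted OT
  surface: dS = dxdy·√(1 + G_x² + G_y²) summed over the mask, plus the
  projected area (the substrate side of the cell is flat). Gradients are
  central differences with edge replication. The discrete sum converges
  as O(√h) at a vertical-tangent rim: the hemisphere check
  (S = 3πr², V = (2/3)πr³) holds to 2 %/1 % at a 600-px diameter, and
  halving the pitch at r = 40 µm moves S by 0.44 % and V by < 0.001 %.
* **Sphericity** — Ψ = 4.84·V^(2/3)/S with V in µm³ and S in µm²
  (4.84 ≈ π^(1/3)·6^(2/3), making Ψ(sphere) = 1); Ψ → 0 for a laminar
  disk. Both limits are evaluated from closed forms in the acceptance
  script.

## Texture

All six statistics use population (1/N) normalization exactly as
printed in the quantitative-phase literature: mean, variance, excess
kurtosis (−3 term), skewness, histogram entropy (−Σp log₂p over 256
equal-width bins spanning the sample min–max, empty bins excluded), and
GLCM energy (angular second moment): the ROI quantized to 16 equal-width
gray levels, co-occurrence at offset (0, 1), symmetrized, normalized to
sum 1, energy = Σp².

The ROI convention matters and is fixed deliberately: all six statistics
are computed on the head-mask bounding box scaled by 1.5, in which the
elliptical head fills ≈35 % of the pixels. In this dome-plus-background
mixture regime the statistics land where head-ROI phase statistics are
reported for real sperm (skewness ≈ +1, entropy ≈ 5–6 bits, mean ≈ 0.9
rad); the head-only marginal is instead left-skewed (≈ −0.6) with
≈7.5-bit entropy, and under the flattening deformation it cannot
reproduce the reported direction pattern at all. The GLCM
interpretation of the double-subscripted "energy" formula and the 16/256
discretizations are package conventions; the source formulas do not
specify them.

Every formula has an independent brute-force oracle (direct summation,
naive pair counting) asserted to 10⁻¹⁰ on random ROIs each test run,
and the co-occurrence counting is cross-checked against
`skimage.feature.graycomatrix`.

## Classification

Eleven predictors per cell: OT_max, S, V, S/V, Ψ, mean, variance,
entropy, kurtosis, skewness, energy. Stratified 60/40 split (seeded);
z-score standardization fitted on the training partition only; SVM with
a linear kernel and C = 1 by default — the smallest assumption, since
no kernel is prescribed by the problem; RBF is available via
configuration. Zero-variance predictors are dropped with a warning and
echoed in the report. The operating point for
sensitivity/specificity/accuracy is decision-score threshold 0; the ROC
sweeps every distinct score plus ±∞ and the AUC is trapezoidal, tested
to equal the Mann–Whitney U statistic exactly and to collapse to
0.5 ± 0.02 under label permutation at n = 2000/class. Because the
real-data literature labels its 89.93 % figure both "area under the ROC
curve" and "accuracy" in different places, reports always emit both,
separately labelled. At the generator defaults (s = 0 vs s = 1) the
classes are strongly separable (AUC ≈ 1.0 on held-out data); with zero
effect size the test AUC calibrates to 0.46–0.54 at n = 200/class.

## What the synthetic validation shows — and does not

Passing tests establish that: the fringe model, reconstruction chain and
every feature formula are implemented correctly (oracle equivalence,
analytic fixtures, round-trip fidelity); the deformation's direction
pattern propagates through the full measurement chain at realistic noise
levels; and the classifier machinery is leak-free and calibrated. They
do **not** establish clinical performance: the phantoms are smooth
parametric shapes without acrosome/nucleus substructure, debris,
overlapping cells, defocus, or refractive-index heterogeneity, the
deformation is a stylized surrogate for H₂O₂ damage, and effect sizes
were chosen to emulate reported directions, not fitted to raw data
(none are deposited). Real-cell accuracies cannot be reproduced or
compared at desk scale.

## Problem sizes and runtime choices

Validation sizes are chosen to keep the full suite in single-digit
minutes on one CPU while leaving comfortable statistical margins: 20
noiseless phantoms for round-trip fidelity, 20 cells/level × 5 levels
for the stress sweep (validated on three independent base seeds during
design), 10 seeds for the noise-regime ordering, 50 random ROIs per
oracle run, 2000/class for the permutation null, and a 600-px
hemisphere. The direction checks compare control vs top-dose medians
(the regime in which the real-data comparisons are reported), with
strict monotonicity across all five levels asserted for maximum phase,
S and Ψ.

## Known limitations

* Physical diffraction/defocus propagation and partial-coherence
  transfer functions are not modelled; the pseudo-thermal regime is an
  additive-noise idealization.
* The Monge sum underestimates steep rims (O(√h)); comparisons across
  conditions are unaffected because the bias is common.
* Segmentation's zero-level extrapolation assumes a cap-like profile;
  heavily deformed or fragmented heads would need a different model.
* Absolute µm-scale values depend on the assumed 0.1 µm pixel pitch;
  only relative comparisons are meaningful.
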