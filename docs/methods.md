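# Methods

This note documents the models, defaults and numerical choices behind
`sfdiq`, and what the synthetic-data generator does and does not emulate.

## Forward reflectance model

The package uses the standard diffusion-approximation reflectance of a
spatially modulated planar source on a semi-infinite homogeneous medium.
A pattern of frequency `fx` (cm⁻¹ on the sample plane; the model consumes
the radial frequency 2π·fx) behaves like a planar source whose attenuation
is stiffened transversely: μeff′(fx) = √(μeff² + (2π fx)²) with
μeff = √(3 μa μtr), μtr = μa + μs′. With the partial-current boundary
condition parameterized by A = (1 − R_eff)/(2(1 + R_eff)),
R_eff ≈ 0.0636 n + 0.668 + 0.710/n − 1.440/n², the diffuse reflectance is

    Rd(fx) = 3 A a′ / ((μeff′/μtr + 1)(μeff′/μtr + 3A)),   a′ = μs′/μtr.

Assumptions: homogeneous semi-infinite medium, scattering-dominated
transport (μs′ ≫ μa, satisfied across the supported tissue range), index-
mismatched planar boundary, no layering. The planar fx = 0 case uses the
same expression with μeff′ = μeff, so Rd is continuous at fx = 0. The
implementation is verified in the test suite against an independent
numerical solution of the same boundary-value problem (`solve_bvp` on the
1-D diffusion ODE) to better than 10⁻⁶ relative error over a
5×5×5 (μa, μs′, fx) grid.

Default refractive index n = 1.4 (typical soft tissue), configurable per
measurement.

## Demodulation

The three-phase amplitude estimator
M_AC = (√2/3)·√[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²] is exact for an ideal
sinusoid sampled at phases 0, 2π/3, 4π/3, independent of the global phase
offset. The dark frame, when supplied, is subtracted first; negative
intensities are clamped to zero (counted in the log) because a negative
sample would otherwise propagate as a complex amplitude. Pixels touching
the detector full-scale value (default 2¹⁶ − 1) in any phase frame are
flagged saturated and excluded from all downstream fitting, since
demodulation of a clipped sinusoid is biased. The DC channel used for
calibration is the fx = 0 frequency's M_AC estimate, keeping every
frequency on the same estimator.

## Calibration and inversion

Calibration forms Rd = (M_AC,sample / M_AC,ref) · Rd_model(fx; ref
properties) per pixel, cancelling gain, illumination and optics. The
default uses the reference per pixel (also corrects illumination
non-uniformity); `ref_mode="mean"` averages the reference field first.
Non-physical values (Rd > 1, non-finite, zero reference amplitude) are
masked rather than clipped, and masked pixels propagate as missing values
into every downstream map — there is no silent in-fill.

Inversion is bounded nonlinear least squares per pixel (trust-region
reflective), bounds μa ∈ [10⁻³, 5] cm⁻¹ and μs′ ∈ [1, 100] cm⁻¹ — spanning
tissue and the calibration-phantom titration range with margin — starting
from (0.5, 15) cm⁻¹. The low- and high-frequency ends of Rd(fx) nearly
decouple μa and μs′, so the problem is benign; an optional 20×20
logarithmic grid pre-scan per pixel guards degenerate curves. Optimizer
tolerances are ftol = xtol = gtol = 10⁻¹², capped at 200 model evaluations
per pixel: at two parameters per pixel the tight tolerances are
essentially free and let noiseless round trips recover parameters to
≲10⁻⁸, which downstream concentration accuracy relies on. Optimizer
failures and pixels with fewer than two usable frequencies are marked
unconverged (NaN), never raised. Optional mean-pool binning of the Rd maps
before fitting (NaN-aware; a binned pixel is valid when any contributor
is) mirrors camera-binning practice, cuts noise and runtime, and is the
default mode used by the acceptance script (factor 8, matching common
laparoscopic acquisition binning).

## Fluorescence correction and calibration

The attenuation correction uses a 1-D effective-pathlength model:
excitation fluence decays as exp(−μeff,ex z) and the escape probability of
emission from depth z as exp(−μeff,em z), so detected fluorescence from a
uniform fluorophore is ∝ C·L with L = 1/(μeff,ex + μeff,em). The
correction factor X_1D = L(pixel)/L(calibration phantom) is therefore 1
under calibration conditions, strictly decreasing in absorption at either
wavelength, and dimensionless; all absolute scale lives in the calibration
curve. Boundary terms (A, R_eff) are omitted — they are absorbed by the
normalization for the homogeneous comparisons the correction is used for.
The formula sits behind a single interface (`correction_factor`) so a more
elaborate empirical pathlength model can be swapped in without touching
the rest of the chain.

The calibration curve is an ordinary least-squares line f_corr = slope·C +
intercept over phantom measurements at known concentrations (the canonical
design uses 2, 4, 6, 8 μg/mL); r² below 0.98 triggers a warning, and a
non-positive slope makes concentration conversion an error. Negative
concentrations are clamped to zero with a logged count. Autofluorescence
is subtracted after correction, as a scalar ROI level or a co-registered
pre-injection map; co-registration between time points is assumed (fixed
camera, stationary subject) and no registration step is implemented.

## Kinetics

ROI polygons rasterize by the pixel-center even-odd rule; explicit boolean
masks are also accepted. Self-intersecting polygons are rejected at
construction. Standard deviations are population (divide by n). The
release-curve plateau call uses consecutive relative increments: the
plateau time is the earliest time after which every subsequent increment
stays below the threshold (default 2%, configurable); a curve whose final
increment still exceeds the threshold reports "not reached". A constant
series plateaus at its first time point by this rule.

## Synthetic-data generator

The generator is the exact inverse of the processing model. Reflectance
frames are I_k = G·[Rd(0) + Rd(fx)·cos(2π fx x + φ_k)] with the sinusoid
along the column axis and the sample-plane sampling declared as
pixels-per-cm (default 40, i.e. a 3.2 cm field across 128 pixels;
frequencies at or beyond Nyquist are rejected). The gain G maps a pixel
with Rd = 0.5 to a sinusoid crest at 60% of full scale, leaving headroom
so realistic phantoms never clip while deliberately brighter scenes
exercise the saturation mask. Fluorescence frames are
F_raw = X_1D·(slope·C + intercept) + background + dark. By construction,
the noiseless pipeline recovers G·Rd(fx), the ground-truth properties and
the ground-truth concentration exactly; this is asserted in the tests.
The default ground-truth calibration line in generated datasets uses a
zero intercept, so that subtracting a pre-injection background frame and
inverting the line compose exactly.

Noise is multiplicative Gaussian (relative, shot-like) plus additive read
noise, clipped to [0, full scale], with every draw owned by a
`numpy` generator seeded from the `NoiseModel`; phantom suites spawn
independent child seeds per phantom so the suite is reproducible as a
whole. The standard study conditions baked into the defaults are the
3×3 titration grid μa ∈ {0.5, 1.0, 1.5} cm⁻¹ × μs′ ∈ {10, 20, 30} cm⁻¹,
the 22-frequency (0–3.1764 cm⁻¹) wide-field and 5-frequency (0–2.5 cm⁻¹)
laparoscopic configurations, 1% multiplicative noise, and 128×128 frames
(fits in seconds on one CPU; the acceptance script uses exactly these).

What the generator does **not** emulate: optical blur / PSF, fiber-bundle
comb artifacts, specular reflections, vignetting, surface curvature and
height variation, layered media (e.g. skin over tumor), depth-resolved
fluorophore distributions, and fluorescence under structured illumination
(fluorescence frames are planar). Passing tests therefore demonstrate
correctness of the estimators and of the correction chain under the stated
homogeneous-semi-infinite model, not robustness to these real-data
effects; on real tissue, layering and curvature are known accuracy limits.

## Design choices

- Demodulation uses the universal three-phase estimator; the acquisition
  format pins exactly three phases per (frequency, wavelength).
- Frequency sets must be strictly increasing and include fx = 0, which
  doubles as the DC/planar channel.
- The stack-file dialect is multi-page float32 TIFF, pages ordered
  phase-fastest then frequency then wavelength, with a JSON sidecar as the
  single source of truth; lengths in cm, frequencies in cm⁻¹, wavelengths
  in nm, concentrations in μg/mL; image coordinates (row, col), 0-based.
- A pipeline configuration is validated before any stage runs (unknown
  keys rejected, inputs must exist); outputs carry the configuration's
  SHA-256 for provenance, and identical configuration + seed reproduce
  byte-identical CSV/JSON outputs.
- A background file given to the pipeline is treated as a pre-injection
  raw frame and is dark-subtracted and X_1D-corrected before subtraction;
  a scalar background is used directly in corrected-fluorescence units.

## Known limitations

- Homogeneous semi-infinite diffusion only; no lookup-table inversion
  (the fitted approach is canonical at these problem sizes), no
  single-snapshot demodulation, no profilometry correction.
- The 1-D pathlength correction ignores boundary reflection terms and
  depth-dependent fluorophore distributions; it is exact only in the
  normalization-anchored regime it is designed for.
- ROI statistics are descriptive (mean ± population std); no hypothesis
  testing between groups.
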