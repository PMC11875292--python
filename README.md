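# sfdiq — quantitative SFDI and attenuation-corrected fluorescence

`sfdiq` is a processing pipeline for **spatial frequency domain imaging
(SFDI)** with quantitative fluorescence readout, aimed at photodynamic-
therapy (PDT) dosimetry and light-triggered drug-release monitoring: it
turns structured-illumination image stacks into per-pixel maps of tissue
absorption (μa) and reduced scattering (μs′), uses those maps to correct
raw fluorescence for tissue attenuation, converts the corrected signal to
absolute fluorophore concentration (μg/mL), and summarizes photobleaching
and release kinetics over regions of interest.

It is written for optical-imaging researchers who have (or simulate)
three-phase, multi-frequency SFDI acquisitions and need a reproducible,
scriptable alternative to interactive processing.

## The model

Sinusoidal patterns at spatial frequency `fx` (cm⁻¹) are projected at three
phases (0, 2π/3, 4π/3). Per pixel, the modulation amplitude is demodulated
as

    M_AC = (√2/3) √[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]

and converted to absolute diffuse reflectance with a reference phantom of
known optical properties:

    Rd(fx) = (M_AC,sample / M_AC,ref) · Rd_model(fx; μa_ref, μs′_ref)

`Rd_model` is the diffusion-approximation reflectance of a semi-infinite
homogeneous medium: with μtr = μa + μs′, a′ = μs′/μtr, μeff = √(3 μa μtr),
μeff′ = √(μeff² + (2π fx)²) and boundary constant
A = (1 − R_eff)/(2(1 + R_eff)),

    Rd(fx) = 3 A a′ / ((μeff′/μtr + 1)(μeff′/μtr + 3A)).

Fitting this curve across frequencies per pixel (bounded nonlinear least
squares) separates μa from μs′. Fluorescence is then corrected by the 1-D
effective-pathlength factor

    X_1D(ex,em) = L(pixel) / L(reference),   L = 1 / (μeff,ex + μeff,em),
    F_corr = F_raw / X_1D,

normalized so X_1D = 1 under the calibration phantom's properties, and a
linear calibration curve (counts per μg/mL) maps F_corr to concentration.

A synthetic-data generator renders the exact inverse of this chain
(structured-illumination stacks, dark frames, planar fluorescence frames,
phantom titration suites) from ground-truth scenes, so the whole pipeline
is testable without an instrument.

## Worked example

A 32×32 scene with a "tumor" disc that has both higher absorption
(μa 1.5 vs 0.3 cm⁻¹) and higher fluorophore content (1.2 vs 1.0 μg/mL)
than its periphery, imaged at 1% noise with the 5-frequency configuration:

```python
import numpy as np
from sfdiq import *

scene = tumor_scene(shape=(32, 32), radius=8)
noise = NoiseModel(multiplicative_sigma=0.01, seed=0)
stack = render_reflectance_stack(scene, LAPAROSCOPIC_FREQUENCIES, noise=noise)

ref_props = OpticalProperties(0.5, 10.0)
ref = render_reflectance_stack(
    flat_scene(0.5, 10.0, shape=(32, 32), wavelengths=scene.wavelengths),
    LAPAROSCOPIC_FREQUENCIES)
phantom = ReferencePhantom({490.0: ref_props, 590.0: ref_props}, demodulate(ref))
rd = calibrate_reflectance(demodulate(stack), phantom)
opm = fit_optical_properties(rd)

slope = 150.0
f_raw, dark = render_fluorescence_frame(scene, 0, 1, (slope, 0.0),
                                        ref_props, ref_props, noise=noise)
x1d = correction_factor(opm.mua[0], opm.musp[0], opm.mua[1], opm.musp[1],
                        ref_props, ref_props)
cal = fit_calibration([2, 4, 6, 8], [slope * c for c in (2, 4, 6, 8)])
conc = to_concentration(correct_fluorescence(f_raw, dark, x1d), cal)

rows, cols = np.mgrid[0:32, 0:32]
tumor = RegionOfInterest("tumor", mask=(rows-16)**2 + (cols-16)**2 <= (8*0.7)**2)
peri = RegionOfInterest("periphery", mask=(rows-16)**2 + (cols-16)**2 >= (8*1.4)**2)
net = f_raw - dark
print(f"raw fluorescence   tumor {roi_stats(net, tumor)[0]:8.1f}  periphery {roi_stats(net, peri)[0]:8.1f}  (a.u.)")
print(f"concentration      tumor {roi_stats(conc, tumor)[0]:8.3f}  periphery {roi_stats(conc, peri)[0]:8.3f}  (ug/mL)")
print(f"contrast ratio (concentration): {contrast_ratio(roi_stats(conc, tumor)[0], roi_stats(conc, peri)[0]):.2f}")
print(f"fitted mua         tumor {roi_stats(opm.mua[0], tumor)[0]:8.3f}  periphery {roi_stats(opm.mua[0], peri)[0]:8.3f}  (cm^-1)")
```

prints

```
raw fluorescence   tumor     91.7  periphery    195.4  (a.u.)
concentration      tumor    1.200  periphery    1.002  (ug/mL)
contrast ratio (concentration): 1.20
fitted mua         tumor    1.503  periphery    0.302  (cm^-1)
```

The raw fluorescence is *inverted* — the absorbing tumor looks dimmer than
its surroundings despite containing more fluorophore — while the
attenuation-corrected concentration map recovers both the true values and
the true positive contrast, and the fitted absorption map matches the
ground truth.

## Command line

```sh
sfdiq simulate --preset tumor --out demo --shape 48 --seed 1
sfdiq run --config demo/config.yaml           # full pipeline
sfdiq demodulate --stack s.tiff --meta s.json --out dem/
sfdiq calibrate --sample dem/ --reference ref/ --ref-props props.yaml --out rd/
sfdiq fit-op --rd rd/ --n 1.4 --binning 8 --out op/
sfdiq correct-fluor --fraw f.tiff --dark d.tiff --op-ex op/ --op-em op/ \
      --ex-nm 490 --em-nm 590 --cal cal.json --out fluor/
sfdiq kinetics --maps manifest.json --roi roi.json --out kin/
```

Stacks are multi-page 32-bit float TIFFs with a JSON sidecar declaring the
(phase, frequency, wavelength) ordering; all frequencies are in cm⁻¹,
wavelengths in nm, concentrations in μg/mL.

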