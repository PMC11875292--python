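"""Synthetic SFDI acquisitions from ground-truth scenes.

Everything the instrument would produce — three-phase structured-
illumination reflectance stacks, dark frames, planar fluorescence frames,
reference- and calibration-phantom datasets — is rendered from ground-truth
optical-property and fluorophore maps, so every pipeline stage is testable
with no hardware and no download.

Rendering is the exact inverse of the processing model.  A reflectance
frame at phase ``phi_k`` and frequency ``fx`` is

    I_k = G * [Rd(0) + Rd(fx) * cos(2 pi fx x + phi_k)]

with ``Rd`` the diffusion forward model at the pixel's ground-truth
properties, ``x`` the sample-plane coordinate along the column axis (cm),
and ``G`` the instrument gain; three-phase demodulation of a noiseless
stack therefore returns exactly ``G * Rd(fx)``.  A fluorescence frame is

    F_raw = X_1D * (slope * C + intercept) + background + dark

the inverse of the attenuation-correction chain, so the noiseless pipeline
recovers ``C`` exactly.  Noise is multiplicative Gaussian (shot-like
relative noise) plus additive read noise, clipped at the detector full
scale; all randomness is owned by a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    DEFAULT_REFRACTIVE_INDEX,
    OpticalProperties,
    WavelengthBand,
    as_frequency_set,
    diffuse_reflectance,
)
from .demod import PHASES, AcquisitionStack
from .fluor import correction_factor

__all__ = [
    "NoiseModel",
    "SyntheticScene",
    "flat_scene",
    "tumor_scene",
    "render_reflectance_stack",
    "render_fluorescence_frame",
    "make_phantom_suite",
    "WIDEFIELD_FREQUENCIES",
    "LAPAROSCOPIC_FREQUENCIES",
    "PHANTOM_GRID_MUA",
    "PHANTOM_GRID_MUSP",
    "DOX_CALIBRATION_UG_ML",
    "default_gain",
]

#: wide-field configuration: 22 spatial frequencies spanning 0-3.1764 cm^-1
WIDEFIELD_FREQUENCIES = np.linspace(0.0, 3.1764, 22)
#: laparoscopic configuration: 5 spatial frequencies spanning 0-2.5 cm^-1
LAPAROSCOPIC_FREQUENCIES = np.linspace(0.0, 2.5, 5)
#: calibration-phantom titration grid (cm^-1)
PHANTOM_GRID_MUA = (0.5, 1.0, 1.5)
PHANTOM_GRID_MUSP = (10.0, 20.0, 30.0)
#: doxorubicin fluorescence-calibration design points (ug/mL)
DOX_CALIBRATION_UG_ML = (2.0, 4.0, 6.0, 8.0)

DEFAULT_SHAPE = (128, 128)
DEFAULT_PIXELS_PER_CM = 40.0  # 3.2 cm field of view across 128 pixels


def default_gain(full_scale: float) -> float:
    """Instrument gain: a pixel with Rd = 0.5 peaks (DC + AC crest) at 60%
    of full scale, leaving headroom so realistic phantoms never clip."""
    return 0.6 * full_scale


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: relative Gaussian + additive read noise, clipped.

    ``multiplicative_sigma`` is the relative noise fraction (0.01 = 1%),
    ``read_sigma`` is in camera units.  All draws come from a generator
    seeded with ``seed``; the same seed reproduces the same frames.
    """

    multiplicative_sigma: float = 0.0
    read_sigma: float = 0.0
    full_scale: float = 2**16 - 1
    seed: int = 0

    def __post_init__(self):
        if self.multiplicative_sigma < 0 or self.read_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = clean
        if self.multiplicative_sigma > 0:
            out = out * (1.0 + self.multiplicative_sigma * rng.standard_normal(out.shape))
        if self.read_sigma > 0:
            out = out + self.read_sigma * rng.standard_normal(out.shape)
        return np.clip(out, 0.0, self.full_scale)


@dataclass
class SyntheticScene:
    """Ground truth: per-wavelength property maps plus a fluorophore map.

    ``mua`` and ``musp`` have shape (W, R, C) in cm^-1; ``fluor`` (R, C)
    in ug/mL; ``background_fluor`` is autofluorescence in camera units
    (scalar or map).
    """

    mua: np.ndarray
    musp: np.ndarray
    wavelengths: tuple
    fluor: np.ndarray | None = None
    background_fluor: float | np.ndarray = 0.0
    n: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self):
        self.mua = np.asarray(self.mua, dtype=float)
        self.musp = np.asarray(self.musp, dtype=float)
        self.wavelengths = tuple(self.wavelengths)
        if self.mua.ndim != 3 or self.mua.shape != self.musp.shape:
            raise ValueError("mua and musp must be (W, R, C) arrays of equal shape")
        if self.mua.shape[0] != len(self.wavelengths):
            raise ValueError("first axis of property maps must match the wavelength list")
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("optical properties must be strictly positive")
        if self.fluor is not None:
            self.fluor = np.asarray(self.fluor, dtype=float)
            if self.fluor.shape != self.mua.shape[1:]:
                raise ValueError("fluor map must match the scene (rows, cols)")
            if np.any(self.fluor < 0):
                raise ValueError("fluorophore concentrations must be >= 0")
        if np.any(np.asarray(self.background_fluor) < 0):
            raise ValueError("background fluorescence must be >= 0")

    @property
    def shape(self) -> tuple:
        return self.mua.shape[1:]

    def props_at(self, w: int) -> tuple:
        """(mua, musp) 2-D ground-truth slices at wavelength index ``w``."""
        return self.mua[w], self.musp[w]


def flat_scene(
    mua,
    musp,
    shape=DEFAULT_SHAPE,
    wavelengths=(WavelengthBand(660.0),),
    fluor: float = 0.0,
    background_fluor: float = 0.0,
    n: float = DEFAULT_REFRACTIVE_INDEX,
) -> SyntheticScene:
    """Homogeneous phantom scene.  ``mua``/``musp`` may be scalars (shared
    across wavelengths) or per-wavelength sequences."""
    nw = len(wavelengths)
    mua_arr = np.broadcast_to(np.reshape(np.asarray(mua, float), (-1, 1, 1)), (nw, *shape)).copy()
    musp_arr = np.broadcast_to(np.reshape(np.asarray(musp, float), (-1, 1, 1)), (nw, *shape)).copy()
    return SyntheticScene(
        mua=mua_arr,
        musp=musp_arr,
        wavelengths=wavelengths,
        fluor=np.full(shape, float(fluor)),
        background_fluor=background_fluor,
        n=n,
    )


def tumor_scene(
    shape=DEFAULT_SHAPE,
    wavelengths=(WavelengthBand(490.0, "excitation"), WavelengthBand(590.0, "emission")),
    center=None,
    radius: float = 14.0,
    mua_periphery: float = 0.3,
    mua_tumor: float = 1.5,
    musp_periphery: float = 10.0,
    musp_tumor: float = 12.0,
    fluor_periphery: float = 1.0,
    fluor_tumor: float = 1.2,
    background_fluor: float = 0.0,
    n: float = DEFAULT_REFRACTIVE_INDEX,
) -> SyntheticScene:
    """Disc "tumor" embedded in homogeneous periphery.

    The defaults give the tumor both higher absorption and (mildly) higher
    fluorophore content than the periphery — the regime where raw
    fluorescence contrast inverts while true concentration contrast stays
    positive, since the attenuation penalty outweighs the concentration
    excess.
    """
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    disc = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
    nw = len(wavelengths)
    mua = np.where(disc, mua_tumor, mua_periphery)[None].repeat(nw, axis=0)
    musp = np.where(disc, musp_tumor, musp_periphery)[None].repeat(nw, axis=0)
    fluor = np.where(disc, fluor_tumor, fluor_periphery)
    return SyntheticScene(
        mua=mua, musp=musp, wavelengths=wavelengths, fluor=fluor,
        background_fluor=background_fluor, n=n,
    )


def render_reflectance_stack(
    scene: SyntheticScene,
    frequencies,
    noise: NoiseModel | None = None,
    pixels_per_cm: float = DEFAULT_PIXELS_PER_CM,
    gain: float | None = None,
    dark_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AcquisitionStack:
    """Render a three-phase structured-illumination reflectance stack.

    The sinusoid runs along the column axis; ``pixels_per_cm`` declares the
    sample-plane sampling so ``fx`` in cm^-1 maps to cycles per pixel.
    Frequencies at or beyond Nyquist (0.5 cycles/pixel) are rejected.
    """
    noise = noise or NoiseModel()
    frequencies = as_frequency_set(frequencies)
    if frequencies[-1] / pixels_per_cm >= 0.5:
        raise ValueError(
            f"max frequency {frequencies[-1]} cm^-1 at {pixels_per_cm} px/cm is at or beyond Nyquist"
        )
    if gain is None:
        gain = default_gain(noise.full_scale)
    rng = rng if rng is not None else noise.rng()

    nw = len(scene.wavelengths)
    nr, nc = scene.shape
    x_cm = np.arange(nc) / pixels_per_cm  # column coordinate on the sample plane

    rd = diffuse_reflectance(
        scene.mua[None], scene.musp[None], frequencies[:, None, None, None], n=scene.n
    )  # (F, W, R, C)
    rd0 = rd[0]  # planar DC reflectance per (W, R, C)

    clean = np.empty((3, frequencies.size, nw, nr, nc))
    for k, phi in enumerate(PHASES):
        carrier = np.cos(2.0 * np.pi * frequencies[:, None] * x_cm[None, :] + phi)  # (F, C)
        clean[k] = gain * (rd0[None] + rd * carrier[:, None, None, :])
    images = noise.apply(clean, rng)

    dark = None
    if dark_level > 0:
        images = np.clip(images + dark_level, 0.0, noise.full_scale)
        dark = np.full((nr, nc), dark_level)
        if noise.read_sigma > 0:
            dark = np.clip(dark + noise.read_sigma * rng.standard_normal(dark.shape), 0.0, noise.full_scale)

    meta = {
        "pixels_per_cm": pixels_per_cm,
        "full_scale": noise.full_scale,
        "gain": gain,
        "exposure_ms": 100.0,
        "binning": 1,
        "seed": noise.seed,
    }
    return AcquisitionStack(
        images=images,
        frequencies=frequencies,
        wavelengths=scene.wavelengths,
        dark=dark,
        meta=meta,
    )


def render_fluorescence_frame(
    scene: SyntheticScene,
    ex_index: int,
    em_index: int,
    cal_truth: tuple,
    ref_props_ex: OpticalProperties,
    ref_props_em: OpticalProperties,
    noise: NoiseModel | None = None,
    dark_level: float = 100.0,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Render a planar raw-fluorescence frame plus its dark frame.

    ``cal_truth = (slope, intercept)`` is the ground-truth calibration line
    in camera units per ug/mL.  The frame is built as
    ``F_raw = X_1D * (slope * C + intercept) + background + dark`` so the
    correction chain recovers ``C`` exactly in the noiseless case.
    """
    if scene.fluor is None:
        raise ValueError("scene has no fluorophore map")
    slope, intercept = cal_truth
    if slope <= 0:
        raise ValueError("ground-truth calibration slope must be positive")
    noise = noise or NoiseModel()
    rng = rng if rng is not None else noise.rng()

    mua_ex, musp_ex = scene.props_at(ex_index)
    mua_em, musp_em = scene.props_at(em_index)
    x1d = correction_factor(mua_ex, musp_ex, mua_em, musp_em, ref_props_ex, ref_props_em)
    signal = x1d * (slope * scene.fluor + intercept) + scene.background_fluor

    f_raw = noise.apply(signal, rng) + dark_level
    f_raw = np.clip(f_raw, 0.0, noise.full_scale)
    dark = np.full(scene.shape, float(dark_level))
    if noise.read_sigma > 0:
        dark = np.clip(dark + noise.read_sigma * rng.standard_normal(dark.shape), 0.0, noise.full_scale)
    return f_raw, dark


def make_phantom_suite(
    mua_values=PHANTOM_GRID_MUA,
    musp_values=PHANTOM_GRID_MUSP,
    frequencies=LAPAROSCOPIC_FREQUENCIES,
    shape=DEFAULT_SHAPE,
    noise: NoiseModel | None = None,
    wavelengths=(WavelengthBand(660.0),),
    pixels_per_cm: float = DEFAULT_PIXELS_PER_CM,
    n: float = DEFAULT_REFRACTIVE_INDEX,
) -> list:
    """Render one flat-field stack per (mua, musp) grid point.

    Returns a list of ``(AcquisitionStack, OpticalProperties)`` pairs in
    row-major grid order; the first grid point doubles as the reference
    phantom.  Each phantom gets an independent child seed spawned from the
    noise model's seed, so the suite is reproducible as a whole.
    """
    mua_values = [float(v) for v in np.atleast_1d(mua_values)]
    musp_values = [float(v) for v in np.atleast_1d(musp_values)]
    if not mua_values or not musp_values:
        raise ValueError("phantom grid is empty")
    noise = noise or NoiseModel()
    children = np.random.SeedSequence(noise.seed).spawn(len(mua_values) * len(musp_values))
    suite = []
    i = 0
    for mua in mua_values:
        for musp in musp_values:
            scene = flat_scene(mua, musp, shape=shape, wavelengths=wavelengths, n=n)
            stack = render_reflectance_stack(
                scene,
                frequencies,
                noise=noise,
                pixels_per_cm=pixels_per_cm,
                rng=np.random.default_rng(children[i]),
            )
            suite.append((stack, OpticalProperties(mua, musp, n)))
            i += 1
    return suite
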