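"""Three-phase demodulation of structured-illumination image stacks.

Each (spatial frequency, wavelength) pair is acquired three times with the
projected sinusoid phase-shifted by 0, 2*pi/3 and 4*pi/3.  The amplitude of
the spatially modulated reflectance component at a pixel is recovered with
the standard three-phase estimator

    M_AC = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)
    M_DC = (I1 + I2 + I3) / 3

which is exact for an ideal sinusoid regardless of its global phase offset.
The dark frame, when present, is subtracted before demodulation; negative
results are clamped to zero (and counted), since a negative intensity would
otherwise propagate as an imaginary amplitude downstream.  Pixels that hit
the detector full-scale value in any phase frame are flagged saturated —
demodulating a clipped sinusoid is biased — and excluded from fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import WavelengthBand, as_frequency_set

__all__ = ["AcquisitionStack", "DemodulatedSet", "demodulate", "DEFAULT_FULL_SCALE"]

logger = logging.getLogger(__name__)

DEFAULT_FULL_SCALE = 2**16 - 1

#: canonical nominal phase offsets (radians)
PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)


@dataclass
class AcquisitionStack:
    """Raw intensity images indexed (phase, frequency, wavelength, row, col).

    Attributes
    ----------
    images : ndarray, shape (3, F, W, R, C)
        Intensity in arbitrary linear camera units; exactly three phase
        images per (frequency, wavelength).
    frequencies : ndarray, shape (F,)
        Spatial frequencies in cm^-1; strictly increasing, starting at 0.
    wavelengths : tuple of WavelengthBand
    dark : ndarray (R, C), optional
        Dark frame in the same units, subtracted before demodulation.
    meta : dict
        Free-form acquisition metadata (exposure_ms, binning, pixels_per_cm,
        full_scale, gain, timestamps ...).
    """

    images: np.ndarray
    frequencies: np.ndarray
    wavelengths: tuple
    dark: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 5:
            raise ValueError(
                f"images must be 5-D (phase, frequency, wavelength, row, col), got {self.images.ndim}-D"
            )
        if self.images.shape[0] != 3:
            raise ValueError(f"exactly 3 phase images required, got {self.images.shape[0]}")
        self.frequencies = as_frequency_set(self.frequencies)
        if self.images.shape[1] != self.frequencies.size:
            raise ValueError(
                f"frequency axis mismatch: images have {self.images.shape[1]}, metadata lists {self.frequencies.size}"
            )
        self.wavelengths = tuple(self.wavelengths)
        for band in self.wavelengths:
            if not isinstance(band, WavelengthBand):
                raise TypeError("wavelengths must be WavelengthBand instances")
        if self.images.shape[2] != len(self.wavelengths):
            raise ValueError(
                f"wavelength axis mismatch: images have {self.images.shape[2]}, metadata lists {len(self.wavelengths)}"
            )
        if self.dark is not None:
            self.dark = np.asarray(self.dark, dtype=float)
            if self.dark.shape != self.images.shape[-2:]:
                raise ValueError(
                    f"dark frame shape {self.dark.shape} does not match image shape {self.images.shape[-2:]}"
                )

    @property
    def shape(self) -> tuple:
        """(rows, cols) of a single frame."""
        return self.images.shape[-2:]


@dataclass
class DemodulatedSet:
    """AC/DC modulation-amplitude maps for one acquisition.

    ``mac`` has shape (F, W, R, C); ``mdc`` (W, R, C) is the three-phase
    mean of the planar fx = 0 frames; ``saturation_mask`` (W, R, C) is True
    where any phase frame at any frequency touched full scale.
    """

    mac: np.ndarray
    mdc: np.ndarray
    saturation_mask: np.ndarray
    frequencies: np.ndarray
    wavelengths: tuple
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.mac.shape[-2:]


def demodulate(stack: AcquisitionStack, full_scale: float | None = None) -> DemodulatedSet:
    """Demodulate a three-phase acquisition into M_AC / M_DC maps.

    Parameters
    ----------
    stack : AcquisitionStack
    full_scale : float, optional
        Detector full-scale value used for saturation flagging.  Defaults
        to ``stack.meta['full_scale']`` or 65535.

    Returns
    -------
    DemodulatedSet
    """
    if full_scale is None:
        full_scale = float(stack.meta.get("full_scale", DEFAULT_FULL_SCALE))

    # saturation is judged on the raw frames, before dark subtraction
    saturated = (stack.images >= full_scale).any(axis=(0, 1))  # (W, R, C)
    n_sat = int(saturated.sum())
    if n_sat:
        logger.warning("%d pixel(s) saturated in at least one phase frame", n_sat)

    imgs = stack.images
    if stack.dark is not None:
        imgs = imgs - stack.dark
        n_neg = int((imgs < 0).sum())
        if n_neg:
            logger.info("dark subtraction clamped %d negative sample(s) to 0", n_neg)
        imgs = np.clip(imgs, 0.0, None)

    i1, i2, i3 = imgs[0], imgs[1], imgs[2]
    mac = (np.sqrt(2.0) / 3.0) * np.sqrt((i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2)
    mdc_all = imgs.mean(axis=0)  # (F, W, R, C)
    mdc = mdc_all[0]  # planar fx = 0 channel

    n_bad = int((mdc_all < mac * (1.0 - 1e-9)).sum())
    if n_bad:
        # physically M_DC >= M_AC for a clean sinusoid; noise can break it
        logger.warning("M_DC < M_AC at %d sample(s); likely noise or clipping", n_bad)

    meta = dict(stack.meta)
    meta["full_scale"] = full_scale
    return DemodulatedSet(
        mac=mac,
        mdc=mdc,
        saturation_mask=saturated,
        frequencies=stack.frequencies.copy(),
        wavelengths=stack.wavelengths,
        meta=meta,
    )
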