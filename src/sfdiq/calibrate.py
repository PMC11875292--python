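"""Reference-phantom calibration of demodulated amplitudes to absolute Rd.

A camera measures M_AC in arbitrary linear units: instrument gain,
illumination power and optics all scale it.  Measuring a reference phantom
of known optical properties under identical settings cancels those factors:

    Rd_sample(fx, lam) = (M_AC,sample / M_AC,ref) * Rd_model(fx; props_ref(lam))

where Rd_model is the diffusion forward model.  The default uses the
reference per pixel, which also corrects illumination non-uniformity; a
``ref_mode="mean"`` variant averages the phantom field first (useful when
the reference acquisition is noisy but flat).

Non-physical results (Rd > 1, non-finite, zero reference amplitude,
saturated pixels) are masked, not clipped, so downstream fits see only
honest data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import OpticalProperties, diffuse_reflectance
from .demod import DemodulatedSet

__all__ = ["ReferencePhantom", "CalibratedReflectance", "calibrate_reflectance"]

logger = logging.getLogger(__name__)


@dataclass
class ReferencePhantom:
    """A phantom of known optical properties measured as a DemodulatedSet.

    ``props_by_wavelength`` maps wavelength center (nm) to
    :class:`OpticalProperties`; it must cover every wavelength used by the
    sample acquisition.
    """

    props_by_wavelength: dict
    demod: DemodulatedSet

    def props_for(self, center_nm: float) -> OpticalProperties:
        try:
            return self.props_by_wavelength[center_nm]
        except KeyError:
            raise KeyError(
                f"reference phantom has no optical properties for {center_nm} nm; "
                f"known wavelengths: {sorted(self.props_by_wavelength)}"
            ) from None


@dataclass
class CalibratedReflectance:
    """Absolute diffuse reflectance maps, (F, W, R, C), NaN where masked."""

    rd: np.ndarray
    valid: np.ndarray
    frequencies: np.ndarray
    wavelengths: tuple
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.rd.shape[-2:]


def calibrate_reflectance(
    sample: DemodulatedSet,
    ref: ReferencePhantom,
    ref_mode: str = "pixel",
) -> CalibratedReflectance:
    """Convert sample M_AC maps to absolute diffuse reflectance.

    Parameters
    ----------
    sample : DemodulatedSet
    ref : ReferencePhantom
        Measured under identical acquisition settings (same frequency and
        wavelength grids, same image shape).
    ref_mode : {"pixel", "mean"}
        Use the reference amplitude per pixel (default) or its spatial
        mean over the field of view.

    Returns
    -------
    CalibratedReflectance
        ``rd`` is NaN and ``valid`` False wherever the reference amplitude
        vanished, either acquisition saturated, or Rd came out non-finite,
        negative, or > 1.
    """
    if ref_mode not in ("pixel", "mean"):
        raise ValueError(f"ref_mode must be 'pixel' or 'mean', got {ref_mode!r}")
    rdem = ref.demod
    if not np.allclose(sample.frequencies, rdem.frequencies):
        raise ValueError("sample and reference frequency sets differ")
    sample_nm = [b.center_nm for b in sample.wavelengths]
    ref_nm = [b.center_nm for b in rdem.wavelengths]
    if sample_nm != ref_nm:
        raise ValueError(f"sample wavelengths {sample_nm} != reference wavelengths {ref_nm}")
    if sample.mac.shape != rdem.mac.shape:
        raise ValueError(f"shape mismatch: sample {sample.mac.shape}, reference {rdem.mac.shape}")

    mac_ref = rdem.mac
    sat_ref = rdem.saturation_mask
    if ref_mode == "mean":
        mac_ref = np.where(sat_ref[None], np.nan, mac_ref)
        mac_ref = np.nanmean(mac_ref, axis=(-2, -1), keepdims=True)
        sat_ref = np.zeros_like(sat_ref)

    # model Rd of the reference phantom, per (frequency, wavelength)
    rd_ref_model = np.empty((sample.frequencies.size, len(sample.wavelengths)))
    for w, band in enumerate(sample.wavelengths):
        props = ref.props_for(band.center_nm)
        rd_ref_model[:, w] = diffuse_reflectance(props.mua, props.musp, sample.frequencies, n=props.n)

    with np.errstate(divide="ignore", invalid="ignore"):
        rd = sample.mac / mac_ref * rd_ref_model[:, :, None, None]

    valid = np.isfinite(rd) & (rd >= 0.0) & (mac_ref > 0.0)
    valid &= ~sample.saturation_mask[None]
    valid &= ~sat_ref[None] if ref_mode == "pixel" else True
    n_over = int((valid & (rd > 1.0)).sum())
    if n_over:
        logger.warning("masked %d pixel-sample(s) with non-physical Rd > 1", n_over)
    valid &= ~(rd > 1.0)
    n_zero = int((~(mac_ref > 0.0)).sum())
    if n_zero:
        logger.warning("reference amplitude is zero at %d sample(s); masked", n_zero)

    rd = np.where(valid, rd, np.nan)
    meta = dict(sample.meta)
    meta["ref_mode"] = ref_mode
    return CalibratedReflectance(
        rd=rd,
        valid=valid,
        frequencies=sample.frequencies.copy(),
        wavelengths=sample.wavelengths,
        meta=meta,
    )
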