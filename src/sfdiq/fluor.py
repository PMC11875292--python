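"""Attenuation-corrected quantitative fluorescence.

Raw fluorescence from turbid media confounds fluorophore content with the
optical properties of the background: excitation light is attenuated on
the way in and emitted light on the way out.  With mu_a and mu_s' known at
both wavelengths (from SFDI), the signal is corrected by an effective
path-length factor computed from a 1-D semi-infinite model.  Excitation
fluence decays as exp(-mueff_ex z) and the escape probability of emission
from depth z as exp(-mueff_em z), so the detected fluorescence from a
uniform fluorophore of concentration C is

    F  ∝  C * ∫0^inf exp(-(mueff_ex + mueff_em) z) dz  =  C * L,
    L  =  1 / (mueff_ex + mueff_em),     mueff = sqrt(3 mua (mua + musp)).

The correction factor is normalized to the calibration phantom's optical
properties, X_1D = L(pixel) / L(calibration), so X_1D = 1 under
calibration conditions and all absolute scale lives in the calibration
curve.  The corrected signal is F_corr = F_raw / X_1D; autofluorescence is
then subtracted and a linear calibration curve (counts per ug/mL) converts
to absolute concentration.  The path-length model sits behind this single
interface so a different effective-pathlength model can be swapped in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_model import OpticalProperties, WavelengthBand

__all__ = [
    "FluorescenceRecord",
    "FluorCalibration",
    "effective_attenuation",
    "correction_factor",
    "correct_fluorescence",
    "subtract_autofluorescence",
    "fit_calibration",
    "to_concentration",
]

logger = logging.getLogger(__name__)


def effective_attenuation(mua, musp):
    """mueff = sqrt(3 mua (mua + musp)), array-friendly (cm^-1)."""
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    return np.sqrt(3.0 * mua * (mua + musp))


@dataclass
class FluorCalibration:
    """Linear map between corrected fluorescence and concentration.

    f_corr = slope * C + intercept, fitted by ordinary least squares on
    phantom measurements at known concentrations (ug/mL).
    """

    known_concentrations: np.ndarray
    measured_fcorr: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    ex_nm: float | None = None
    em_nm: float | None = None
    ref_props: dict = field(default_factory=dict)


@dataclass
class FluorescenceRecord:
    """All stages of one (excitation, emission) fluorescence measurement."""

    f_raw: np.ndarray
    ex_band: WavelengthBand
    em_band: WavelengthBand
    x1d: np.ndarray | None = None
    f_corr: np.ndarray | None = None
    concentration: np.ndarray | None = None
    autofluorescence_fraction: float | None = None
    meta: dict = field(default_factory=dict)


def correction_factor(
    mua_ex,
    musp_ex,
    mua_em,
    musp_em,
    ref_props_ex: OpticalProperties,
    ref_props_em: OpticalProperties,
):
    """Per-pixel attenuation-correction factor X_1D(ex, em).

    Parameters
    ----------
    mua_ex, musp_ex : ndarray
        Optical-property maps at the excitation wavelength (cm^-1); NaN at
        unconverged pixels.
    mua_em, musp_em : ndarray
        Same at the emission wavelength.
    ref_props_ex, ref_props_em : OpticalProperties
        Calibration-phantom properties at the two wavelengths; X_1D = 1
        when a pixel matches them.

    Returns
    -------
    ndarray
        X_1D map; NaN wherever inputs are NaN/non-positive.
    """
    mua_ex = np.asarray(mua_ex, dtype=float)
    musp_ex = np.asarray(musp_ex, dtype=float)
    mua_em = np.asarray(mua_em, dtype=float)
    musp_em = np.asarray(musp_em, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (
            ~np.isfinite(mua_ex) | ~np.isfinite(musp_ex) | ~np.isfinite(mua_em) | ~np.isfinite(musp_em)
            | (mua_ex <= 0) | (musp_ex <= 0) | (mua_em <= 0) | (musp_em <= 0)
        )
        total = effective_attenuation(mua_ex, musp_ex) + effective_attenuation(mua_em, musp_em)
    ref_total = (
        effective_attenuation(ref_props_ex.mua, ref_props_ex.musp)
        + effective_attenuation(ref_props_em.mua, ref_props_em.musp)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        x1d = ref_total / total  # = L(pixel) / L(ref)
    x1d = np.where(bad | ~(total > 0), np.nan, x1d)
    return x1d


def correct_fluorescence(f_raw, dark, x1d):
    """F_corr = max(F_raw - dark, 0) / X_1D, masked where X_1D is NaN."""
    f_raw = np.asarray(f_raw, dtype=float)
    x1d = np.asarray(x1d, dtype=float)
    if dark is None:
        dark = 0.0
    dark = np.asarray(dark, dtype=float)
    if dark.ndim and dark.shape != f_raw.shape:
        raise ValueError(f"dark shape {dark.shape} does not match f_raw shape {f_raw.shape}")
    if x1d.shape != f_raw.shape:
        raise ValueError(f"x1d shape {x1d.shape} does not match f_raw shape {f_raw.shape}")
    net = np.clip(f_raw - dark, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_corr = net / x1d
    return np.where(np.isfinite(x1d) & (x1d > 0), f_corr, np.nan)


def subtract_autofluorescence(f_corr, background, roi_mask=None):
    """Remove the tissue's intrinsic (pre-injection) fluorescence.

    Parameters
    ----------
    f_corr : ndarray
        Corrected fluorescence map.
    background : ndarray or float
        Pre-injection corrected-fluorescence map acquired under identical
        settings and co-registered, or a scalar ROI level.
    roi_mask : ndarray of bool, optional
        Region over which the autofluorescence fraction diagnostic is
        computed; defaults to all finite pixels.

    Returns
    -------
    (f_signal, autofluorescence_fraction)
        ``f_signal = max(f_corr - background, 0)``; the fraction is
        mean(background) / mean(f_corr) over the ROI.
    """
    f_corr = np.asarray(f_corr, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.ndim and background.shape != f_corr.shape:
        raise ValueError(f"background shape {background.shape} does not match {f_corr.shape}")
    if roi_mask is None:
        roi_mask = np.isfinite(f_corr)
    bg_in_roi = background if background.ndim == 0 else background[roi_mask]
    with np.errstate(invalid="ignore"):
        denom = float(np.nanmean(f_corr[roi_mask])) if roi_mask.any() else np.nan
        num = float(np.nanmean(bg_in_roi))
    fraction = num / denom if denom and np.isfinite(denom) and denom != 0 else np.nan
    f_signal = np.clip(f_corr - background, 0.0, None)
    f_signal = np.where(np.isfinite(f_corr), f_signal, np.nan)
    over = (background > f_corr) if background.ndim else (background > f_corr)
    n_roi = int(np.count_nonzero(roi_mask))
    if n_roi and np.count_nonzero(over & roi_mask) > 0.5 * n_roi:
        logger.warning("background exceeds signal over more than half of the ROI")
    return f_signal, fraction


def fit_calibration(
    known_concentrations,
    measured_fcorr,
    ex_nm: float | None = None,
    em_nm: float | None = None,
    ref_props: dict | None = None,
) -> FluorCalibration:
    """Ordinary least-squares calibration line f_corr = slope * C + intercept."""
    conc = np.asarray(known_concentrations, dtype=float).ravel()
    fcorr = np.asarray(measured_fcorr, dtype=float).ravel()
    if conc.size != fcorr.size:
        raise ValueError("concentration and fluorescence lists differ in length")
    if conc.size < 2 or np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations to fit a calibration line")
    fit = stats.linregress(conc, fcorr)
    r2 = float(fit.rvalue**2)
    if fit.slope <= 0:
        logger.warning("calibration slope is non-positive (%.4g); curve unusable", fit.slope)
    if r2 < 0.98:
        logger.warning("calibration r^2 = %.4f is below 0.98; check phantom data", r2)
    return FluorCalibration(
        known_concentrations=conc,
        measured_fcorr=fcorr,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        ex_nm=ex_nm,
        em_nm=em_nm,
        ref_props=dict(ref_props or {}),
    )


def to_concentration(f_signal, cal: FluorCalibration):
    """Invert the calibration line: C = (f_signal - intercept) / slope.

    Negative concentrations are clamped to 0 (and counted); NaN pixels
    propagate.
    """
    if cal.slope <= 0:
        raise ValueError(f"calibration slope must be positive, got {cal.slope}")
    f_signal = np.asarray(f_signal, dtype=float)
    conc = (f_signal - cal.intercept) / cal.slope
    n_clamped = int(np.count_nonzero(conc < 0))
    if n_clamped:
        logger.info("clamped %d negative concentration value(s) to 0", n_clamped)
    conc = np.clip(conc, 0.0, None)
    return np.where(np.isfinite(f_signal), conc, np.nan)
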