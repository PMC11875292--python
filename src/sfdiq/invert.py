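"""Pixel-by-pixel inversion of calibrated Rd(fx) curves for mu_a and mu_s'.

For every pixel and wavelength the measured reflectance across all usable
spatial frequencies is fitted, by bounded nonlinear least squares, against
the diffusion forward model:

    (mua*, musp*) = argmin sum_fx [Rd_meas(fx) - Rd_model(fx; mua, musp)]^2

The low-frequency end of the curve is dominated by absorption and the
high-frequency end by scattering, so the two parameters are well separated
for any frequency set that spans both regimes; the default starting point
(0.5, 15) cm^-1 converges reliably over the tissue range.  An optional
coarse log-grid pre-scan per pixel guards against degenerate curves.

Pixels with fewer than two usable frequencies, or where the optimizer
fails, are marked unconverged and carry NaN; they propagate as missing
values into every downstream map (no silent in-fill).  Optional mean-pool
binning of the Rd maps before fitting trades resolution for noise and
runtime, mirroring common camera-binning practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .calibrate import CalibratedReflectance
from .core_model import DEFAULT_REFRACTIVE_INDEX, boundary_coefficient

__all__ = [
    "OpticalPropertyMap",
    "fit_optical_properties",
    "bin_reflectance",
    "DEFAULT_BOUNDS",
    "DEFAULT_INIT",
]

logger = logging.getLogger(__name__)

#: (mua, musp) box, cm^-1 — spans tissue and calibration-phantom ranges with margin
DEFAULT_BOUNDS = ((1e-3, 5.0), (1.0, 100.0))
DEFAULT_INIT = (0.5, 15.0)


@dataclass
class OpticalPropertyMap:
    """Per-pixel, per-wavelength absorption and reduced-scattering maps.

    ``mua`` and ``musp`` have shape (W, R, C) in cm^-1; unconverged pixels
    are NaN with ``converged`` False and must be excluded from ROI
    statistics.  ``residual_norm`` is the 2-norm of the fit residual.
    """

    mua: np.ndarray
    musp: np.ndarray
    residual_norm: np.ndarray
    converged: np.ndarray
    n_used: float
    wavelengths: tuple
    meta: dict = field(default_factory=dict)

    def at_wavelength(self, index: int):
        """(mua, musp, converged) 2-D slices for one wavelength index."""
        return self.mua[index], self.musp[index], self.converged[index]

    def convergence_rate(self) -> float:
        return float(self.converged.mean())


def bin_reflectance(rd: CalibratedReflectance, factor: int) -> CalibratedReflectance:
    """Mean-pool Rd maps by ``factor`` x ``factor`` blocks (NaN-aware).

    Trailing rows/columns that do not fill a block are cropped.  A binned
    pixel is valid when at least one contributing pixel was valid.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"binning factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rd
    nf, nw, nr, nc = rd.rd.shape
    rr, cc = (nr // factor) * factor, (nc // factor) * factor
    if rr == 0 or cc == 0:
        raise ValueError(f"image {nr}x{nc} too small for binning factor {factor}")
    blocks = rd.rd[:, :, :rr, :cc].reshape(nf, nw, rr // factor, factor, cc // factor, factor)
    with np.errstate(invalid="ignore"):
        pooled = np.nanmean(blocks, axis=(3, 5))
    vblocks = rd.valid[:, :, :rr, :cc].reshape(nf, nw, rr // factor, factor, cc // factor, factor)
    valid = vblocks.any(axis=(3, 5))
    pooled = np.where(valid, pooled, np.nan)
    meta = dict(rd.meta)
    meta["binning"] = meta.get("binning", 1) * factor
    if "pixels_per_cm" in meta:
        meta["pixels_per_cm"] = meta["pixels_per_cm"] / factor
    return CalibratedReflectance(
        rd=pooled,
        valid=valid,
        frequencies=rd.frequencies.copy(),
        wavelengths=rd.wavelengths,
        meta=meta,
    )


def _prescan(freqs, y, bounds, a_bound, n_grid=20):
    """Coarse log-grid scan for a robust starting point."""
    mua_g = np.geomspace(bounds[0][0], bounds[0][1], n_grid)
    musp_g = np.geomspace(bounds[1][0], bounds[1][1], n_grid)
    mua2, musp2 = np.meshgrid(mua_g, musp_g, indexing="ij")
    model = _rd_model(mua2[..., None], musp2[..., None], freqs, a_bound)
    cost = ((model - y) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    return float(mua_g[i]), float(musp_g[j])


def _rd_model(mua, musp, freqs, a_bound):
    # inlined forward model without validation, for tight fitting loops
    mutr = mua + musp
    beta = np.sqrt(3.0 * mua * mutr + (2.0 * np.pi * freqs) ** 2) / mutr
    return 3.0 * a_bound * (musp / mutr) / ((beta + 1.0) * (beta + 3.0 * a_bound))


def fit_optical_properties(
    rd: CalibratedReflectance,
    n: float = DEFAULT_REFRACTIVE_INDEX,
    bounds=DEFAULT_BOUNDS,
    init=DEFAULT_INIT,
    binning: int = 1,
    prescan: bool = False,
    max_nfev: int = 200,
) -> OpticalPropertyMap:
    """Fit (mua, musp) at every pixel and wavelength of a calibrated set.

    Parameters
    ----------
    rd : CalibratedReflectance
    n : float
        Refractive index assumed for the forward model.
    bounds : ((mua_lo, mua_hi), (musp_lo, musp_hi))
        Fit box in cm^-1.
    init : (mua0, musp0)
        Starting point; clipped into the bounds.
    binning : int
        Mean-pool the Rd maps by this factor before fitting.
    prescan : bool
        Evaluate a coarse 20x20 log grid per pixel to pick the starting
        point (guards against degenerate curves; slower).
    max_nfev : int
        Cap on forward-model evaluations per pixel.

    Returns
    -------
    OpticalPropertyMap
        On the (possibly binned) grid; unconverged pixels are NaN.
    """
    (mua_lo, mua_hi), (musp_lo, musp_hi) = bounds
    if not (0 < mua_lo < mua_hi and 0 < musp_lo < musp_hi):
        raise ValueError(f"invalid bounds {bounds}")
    rd = bin_reflectance(rd, binning)
    a_bound = float(boundary_coefficient(n))
    freqs = rd.frequencies
    nf, nw, nr, nc = rd.rd.shape

    x0_default = np.clip(init, [mua_lo, musp_lo], [mua_hi, musp_hi])
    lo = np.array([mua_lo, musp_lo])
    hi = np.array([mua_hi, musp_hi])

    mua = np.full((nw, nr, nc), np.nan)
    musp = np.full((nw, nr, nc), np.nan)
    resid = np.full((nw, nr, nc), np.nan)
    converged = np.zeros((nw, nr, nc), dtype=bool)

    for w in range(nw):
        for r in range(nr):
            for c in range(nc):
                use = rd.valid[:, w, r, c]
                if use.sum() < 2:
                    continue
                f_use = freqs[use]
                y = rd.rd[use, w, r, c]
                x0 = np.asarray(_prescan(f_use, y, bounds, a_bound) if prescan else x0_default, dtype=float)
                try:
                    sol = least_squares(
                        lambda x: _rd_model(x[0], x[1], f_use, a_bound) - y,
                        x0,
                        bounds=(lo, hi),
                        method="trf",
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                        max_nfev=max_nfev,
                    )
                except Exception:  # optimizer failure never escapes the pixel loop
                    logger.exception("fit failed at pixel (%d, %d, %d)", w, r, c)
                    continue
                if not sol.success and sol.status <= 0:
                    continue
                mua[w, r, c] = sol.x[0]
                musp[w, r, c] = sol.x[1]
                resid[w, r, c] = float(np.linalg.norm(sol.fun))
                converged[w, r, c] = True

    rate = converged.mean() if converged.size else 0.0
    logger.info("fit converged at %.1f%% of pixels", 100 * rate)
    meta = dict(rd.meta)
    meta.update({"n": n, "bounds": bounds, "init": tuple(np.asarray(init, float))})
    return OpticalPropertyMap(
        mua=mua,
        musp=musp,
        residual_norm=resid,
        converged=converged,
        n_used=n,
        wavelengths=rd.wavelengths,
        meta=meta,
    )
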