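"""Domain types and the analytical diffuse-reflectance forward model.

Spatial-frequency-domain imaging (SFDI) projects sinusoidal illumination
patterns of spatial frequency ``fx`` (cm^-1) onto turbid media and measures
the demodulated diffuse reflectance ``Rd(fx)``.  In the diffusion
approximation for a semi-infinite homogeneous medium, a modulated planar
source behaves like a planar source whose effective attenuation coefficient
is stiffened by the transverse frequency:

    mu_tr      = mu_a + mu_s'               (transport coefficient)
    a'         = mu_s' / mu_tr              (reduced albedo)
    mu_eff     = sqrt(3 mu_a mu_tr)
    mu_eff'    = sqrt(mu_eff^2 + (2 pi fx)^2)
    Rd(fx)     = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3A))

where ``A`` is the boundary proportionality constant derived from the
effective Fresnel reflection coefficient of the air/tissue interface,

    R_eff = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2
    A     = (1 - R_eff) / (2 (1 + R_eff)).

Because low frequencies sense absorption and high frequencies sense
scattering, fitting this curve across a set of frequencies separates
``mu_a`` from ``mu_s'`` per pixel.  The planar (fx = 0) case is the same
expression with ``mu_eff' = mu_eff``; no separate semi-infinite formula is
used, so ``Rd`` is continuous at fx = 0.

All lengths are in cm, spatial frequencies in cm^-1 of the projected
pattern on the sample plane (the model consumes the radial frequency
``2 pi fx``), wavelengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_REFRACTIVE_INDEX",
    "OpticalProperties",
    "WavelengthBand",
    "WAVELENGTH_ROLES",
    "as_frequency_set",
    "effective_reflection_coefficient",
    "boundary_coefficient",
    "diffuse_reflectance",
    "forward_reflectance",
]

DEFAULT_REFRACTIVE_INDEX = 1.4

WAVELENGTH_ROLES = frozenset({"reflectance", "excitation", "emission", "treatment"})


def effective_reflection_coefficient(n):
    """Effective Fresnel reflection coefficient R_eff of the boundary.

    Empirical polynomial fit in the relative refractive index ``n`` (tissue
    over air), valid for n >= 1.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("refractive index must be >= 1")
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def boundary_coefficient(n):
    """Partial-current boundary constant A = (1 - R_eff) / (2 (1 + R_eff))."""
    r_eff = effective_reflection_coefficient(n)
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a homogeneous medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient in cm^-1 (> 0).
    musp : float
        Reduced scattering coefficient in cm^-1 (> 0).
    n : float
        Refractive index of the medium (>= 1); default 1.4, typical of
        soft tissue.
    """

    mua: float
    musp: float
    n: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self):
        if not (np.isfinite(self.mua) and self.mua > 0):
            raise ValueError(f"mua must be a positive finite number, got {self.mua}")
        if not (np.isfinite(self.musp) and self.musp > 0):
            raise ValueError(f"musp must be a positive finite number, got {self.musp}")
        if not (np.isfinite(self.n) and self.n >= 1):
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mutr(self) -> float:
        """Transport coefficient mu_a + mu_s' (cm^-1)."""
        return self.mua + self.musp

    @property
    def albedo(self) -> float:
        """Reduced albedo a' = mu_s' / mu_tr."""
        return self.musp / self.mutr

    @property
    def mueff(self) -> float:
        """Effective attenuation coefficient sqrt(3 mu_a mu_tr) (cm^-1)."""
        return float(np.sqrt(3.0 * self.mua * self.mutr))


@dataclass(frozen=True)
class WavelengthBand:
    """A spectral band identified by its center wavelength and its role."""

    center_nm: float
    role: str = "reflectance"

    def __post_init__(self):
        if not (np.isfinite(self.center_nm) and self.center_nm > 0):
            raise ValueError(f"center_nm must be positive, got {self.center_nm}")
        if self.role not in WAVELENGTH_ROLES:
            raise ValueError(f"unknown wavelength role {self.role!r}; expected one of {sorted(WAVELENGTH_ROLES)}")


def as_frequency_set(frequencies) -> np.ndarray:
    """Validate and return a frequency set as a float array (cm^-1).

    A frequency set is strictly increasing, non-negative, and contains the
    planar fx = 0 term (required downstream as the DC channel).
    """
    fx = np.asarray(frequencies, dtype=float).ravel()
    if fx.size == 0:
        raise ValueError("frequency set is empty")
    if not np.all(np.isfinite(fx)):
        raise ValueError("frequency set contains non-finite values")
    if np.any(fx < 0):
        raise ValueError("spatial frequencies must be >= 0")
    if np.any(np.diff(fx) <= 0):
        raise ValueError("frequency set must be strictly increasing")
    if fx[0] != 0.0:
        raise ValueError("frequency set must contain fx = 0 (the planar/DC term)")
    return fx


def diffuse_reflectance(mua, musp, fx, n=DEFAULT_REFRACTIVE_INDEX):
    """Diffuse reflectance Rd(fx; mu_a, mu_s') of a semi-infinite medium.

    Array-friendly: ``mua``, ``musp``, ``fx`` and ``n`` broadcast against
    each other.  Inputs are in cm^-1; ``fx`` is the pattern frequency in
    cm^-1 (the radial frequency 2*pi*fx enters the model).

    Returns the dimensionless reflectance in [0, 1).
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("mua and musp must be strictly positive")
    if np.any(fx < 0):
        raise ValueError("spatial frequency must be >= 0")
    a_bound = boundary_coefficient(n)
    mutr = mua + musp
    albedo = musp / mutr
    mueff = np.sqrt(3.0 * mua * mutr)
    mueff_prime = np.sqrt(mueff**2 + (2.0 * np.pi * fx) ** 2)
    beta = mueff_prime / mutr
    return 3.0 * a_bound * albedo / ((beta + 1.0) * (beta + 3.0 * a_bound))


def forward_reflectance(props: OpticalProperties, fx):
    """Forward model Rd(fx) for one set of optical properties.

    Thin wrapper over :func:`diffuse_reflectance` taking an
    :class:`OpticalProperties`; ``fx`` may be a scalar or array (cm^-1).
    """
    return diffuse_reflectance(props.mua, props.musp, fx, n=props.n)
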