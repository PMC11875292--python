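"""File formats binding the pipeline stages together.

Conventions (declared in every sidecar):
  - image stacks: multi-page 32-bit float TIFF, pages ordered phase-fastest,
    then frequency, then wavelength; a JSON sidecar is the single source of
    truth for the ordering and the physical axes
  - lengths in cm, spatial frequencies in cm^-1, wavelengths in nm,
    concentrations in ug/mL
  - image coordinates are (row, col), 0-based, row 0 at top
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibrate import CalibratedReflectance
from .core_model import OpticalProperties, WavelengthBand
from .demod import AcquisitionStack, DemodulatedSet
from .fluor import FluorCalibration
from .invert import OpticalPropertyMap
from .kinetics import KineticsSeries, RegionOfInterest

__all__ = [
    "save_stack",
    "load_stack",
    "save_demodulated",
    "load_demodulated",
    "save_calibrated",
    "load_calibrated",
    "save_property_map",
    "load_property_map",
    "load_reference_props",
    "save_calibration",
    "load_calibration",
    "load_roi",
    "save_kinetics",
]

_UNITS = {"length": "cm", "frequency": "cm^-1", "wavelength": "nm", "concentration": "ug/mL"}


def _bands_to_json(wavelengths):
    return [{"center_nm": b.center_nm, "role": b.role} for b in wavelengths]


def _bands_from_json(entries):
    return tuple(WavelengthBand(e["center_nm"], e.get("role", "reflectance")) for e in entries)


def _write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def save_stack(stack: AcquisitionStack, tiff_path, meta_path, dark_path=None) -> None:
    """Write an acquisition stack as multi-page TIFF + JSON sidecar."""
    n_phase, nf, nw, nr, nc = stack.images.shape
    pages = np.transpose(stack.images, (2, 1, 0, 3, 4)).reshape(-1, nr, nc)
    tifffile.imwrite(tiff_path, pages.astype(np.float32))
    if stack.dark is not None:
        if dark_path is None:
            dark_path = Path(tiff_path).with_name(Path(tiff_path).stem + "_dark.tiff")
        tifffile.imwrite(dark_path, stack.dark.astype(np.float32))
    meta = {
        "order": "wavelength,frequency,phase (phase fastest)",
        "phases_rad": [0.0, 2 * np.pi / 3, 4 * np.pi / 3],
        "frequencies_cm1": list(map(float, stack.frequencies)),
        "wavelengths": _bands_to_json(stack.wavelengths),
        "dark_frame": str(dark_path) if stack.dark is not None else None,
        "units": _UNITS,
        **{k: v for k, v in stack.meta.items()},
    }
    _write_json(meta_path, meta)


def load_stack(tiff_path, meta_path) -> AcquisitionStack:
    meta = json.loads(Path(meta_path).read_text())
    pages = tifffile.imread(tiff_path).astype(float)
    freqs = np.asarray(meta["frequencies_cm1"], dtype=float)
    bands = _bands_from_json(meta["wavelengths"])
    nf, nw = freqs.size, len(bands)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != 3 * nf * nw:
        raise ValueError(
            f"{tiff_path}: {pages.shape[0]} pages, expected 3*{nf}*{nw} per sidecar {meta_path}"
        )
    nr, nc = pages.shape[-2:]
    images = pages.reshape(nw, nf, 3, nr, nc).transpose(2, 1, 0, 3, 4)
    dark = None
    if meta.get("dark_frame"):
        dark = tifffile.imread(meta["dark_frame"]).astype(float)
    extra = {
        k: v
        for k, v in meta.items()
        if k not in {"order", "phases_rad", "frequencies_cm1", "wavelengths", "dark_frame", "units"}
    }
    return AcquisitionStack(images=images, frequencies=freqs, wavelengths=bands, dark=dark, meta=extra)


def save_demodulated(dset: DemodulatedSet, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nf, nw, nr, nc = dset.mac.shape
    tifffile.imwrite(out / "mac.tiff", dset.mac.transpose(1, 0, 2, 3).reshape(-1, nr, nc).astype(np.float32))
    tifffile.imwrite(out / "mdc.tiff", dset.mdc.astype(np.float32))
    tifffile.imwrite(out / "saturation.tiff", dset.saturation_mask.astype(np.uint8))
    meta = {
        "order": "wavelength,frequency",
        "frequencies_cm1": list(map(float, dset.frequencies)),
        "wavelengths": _bands_to_json(dset.wavelengths),
        "units": _UNITS,
        **dset.meta,
    }
    _write_json(out / "meta.json", meta)


def load_demodulated(in_dir) -> DemodulatedSet:
    d = Path(in_dir)
    meta = json.loads((d / "meta.json").read_text())
    freqs = np.asarray(meta["frequencies_cm1"], dtype=float)
    bands = _bands_from_json(meta["wavelengths"])
    pages = tifffile.imread(d / "mac.tiff").astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    nr, nc = pages.shape[-2:]
    mac = pages.reshape(len(bands), freqs.size, nr, nc).transpose(1, 0, 2, 3)
    mdc = tifffile.imread(d / "mdc.tiff").astype(float)
    if mdc.ndim == 2:
        mdc = mdc[None]
    sat = tifffile.imread(d / "saturation.tiff").astype(bool)
    if sat.ndim == 2:
        sat = sat[None]
    extra = {k: v for k, v in meta.items() if k not in {"order", "frequencies_cm1", "wavelengths", "units"}}
    return DemodulatedSet(mac=mac, mdc=mdc, saturation_mask=sat, frequencies=freqs, wavelengths=bands, meta=extra)


def save_calibrated(cal: CalibratedReflectance, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nf, nw, nr, nc = cal.rd.shape
    tifffile.imwrite(out / "rd.tiff", cal.rd.transpose(1, 0, 2, 3).reshape(-1, nr, nc).astype(np.float32))
    meta = {
        "order": "wavelength,frequency",
        "frequencies_cm1": list(map(float, cal.frequencies)),
        "wavelengths": _bands_to_json(cal.wavelengths),
        "masked": "NaN pixels are masked (non-physical or unusable)",
        "units": _UNITS,
        **cal.meta,
    }
    _write_json(out / "meta.json", meta)


def load_calibrated(in_dir) -> CalibratedReflectance:
    d = Path(in_dir)
    meta = json.loads((d / "meta.json").read_text())
    freqs = np.asarray(meta["frequencies_cm1"], dtype=float)
    bands = _bands_from_json(meta["wavelengths"])
    pages = tifffile.imread(d / "rd.tiff").astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    nr, nc = pages.shape[-2:]
    rd = pages.reshape(len(bands), freqs.size, nr, nc).transpose(1, 0, 2, 3)
    extra = {k: v for k, v in meta.items() if k not in {"order", "frequencies_cm1", "wavelengths", "masked", "units"}}
    return CalibratedReflectance(
        rd=rd, valid=np.isfinite(rd), frequencies=freqs, wavelengths=bands, meta=extra
    )


def save_property_map(opmap: OpticalPropertyMap, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "mua.tiff", opmap.mua.astype(np.float32))
    tifffile.imwrite(out / "musp.tiff", opmap.musp.astype(np.float32))
    tifffile.imwrite(out / "residual.tiff", opmap.residual_norm.astype(np.float32))
    tifffile.imwrite(out / "converged.tiff", opmap.converged.astype(np.uint8))
    rows = []
    for w, band in enumerate(opmap.wavelengths):
        conv = opmap.converged[w]
        res = opmap.residual_norm[w][conv]
        rows.append(
            {
                "wavelength_nm": band.center_nm,
                "n_pixels": int(conv.size),
                "n_converged": int(conv.sum()),
                "convergence_rate": float(conv.mean()),
                "residual_q50": float(np.median(res)) if res.size else np.nan,
                "residual_q90": float(np.quantile(res, 0.9)) if res.size else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(out / "fit_summary.csv", index=False)
    meta = {
        "wavelengths": _bands_to_json(opmap.wavelengths),
        "n_used": opmap.n_used,
        "units": _UNITS,
        **{k: v for k, v in opmap.meta.items() if k not in {"bounds", "init"}},
    }
    _write_json(out / "meta.json", meta)


def load_property_map(in_dir) -> OpticalPropertyMap:
    d = Path(in_dir)
    meta = json.loads((d / "meta.json").read_text())
    bands = _bands_from_json(meta["wavelengths"])

    def _wl(name):
        arr = tifffile.imread(d / name).astype(float)
        return arr[None] if arr.ndim == 2 else arr

    mua, musp, resid = _wl("mua.tiff"), _wl("musp.tiff"), _wl("residual.tiff")
    conv = _wl("converged.tiff").astype(bool)
    extra = {k: v for k, v in meta.items() if k not in {"wavelengths", "n_used", "units"}}
    return OpticalPropertyMap(
        mua=mua, musp=musp, residual_norm=resid, converged=conv,
        n_used=float(meta["n_used"]), wavelengths=bands, meta=extra,
    )


def load_reference_props(yaml_path) -> dict:
    """Reference-phantom optical properties from YAML.

    Schema: ``{wavelength_nm: {mua_cm1: ..., musp_cm1: ..., n: ...}}``.
    Returns a dict mapping float nm -> OpticalProperties.
    """
    raw = yaml.safe_load(Path(yaml_path).read_text())
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{yaml_path}: expected a mapping wavelength_nm -> properties")
    out = {}
    for nm, entry in raw.items():
        unknown = set(entry) - {"mua_cm1", "musp_cm1", "n"}
        if unknown:
            raise ValueError(f"{yaml_path}: unknown keys {sorted(unknown)} for wavelength {nm}")
        out[float(nm)] = OpticalProperties(
            mua=float(entry["mua_cm1"]),
            musp=float(entry["musp_cm1"]),
            n=float(entry.get("n", 1.4)),
        )
    return out


def save_calibration(cal: FluorCalibration, path) -> None:
    _write_json(
        path,
        {
            "concentrations_ug_ml": list(map(float, cal.known_concentrations)),
            "fcorr_values": list(map(float, cal.measured_fcorr)),
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r2": cal.r_squared,
            "ex_nm": cal.ex_nm,
            "em_nm": cal.em_nm,
            "ref_props": cal.ref_props,
        },
    )


def load_calibration(path) -> FluorCalibration:
    d = json.loads(Path(path).read_text())
    return FluorCalibration(
        known_concentrations=np.asarray(d["concentrations_ug_ml"], dtype=float),
        measured_fcorr=np.asarray(d["fcorr_values"], dtype=float),
        slope=float(d["slope"]),
        intercept=float(d["intercept"]),
        r_squared=float(d["r2"]),
        ex_nm=d.get("ex_nm"),
        em_nm=d.get("em_nm"),
        ref_props=d.get("ref_props", {}),
    )


def load_roi(path) -> RegionOfInterest:
    """ROI from JSON: ``{name, vertices: [[row, col], ...]}`` or
    ``{name, mask_tiff: path}`` (path relative to the JSON file)."""
    p = Path(path)
    d = json.loads(p.read_text())
    name = d.get("name", p.stem)
    if "vertices" in d:
        return RegionOfInterest(name=name, vertices=np.asarray(d["vertices"], dtype=float))
    if "mask_tiff" in d:
        mask = tifffile.imread(p.parent / d["mask_tiff"]).astype(bool)
        return RegionOfInterest(name=name, mask=mask)
    raise ValueError(f"{path}: ROI JSON needs 'vertices' or 'mask_tiff'")


def save_kinetics(series: KineticsSeries, csv_path) -> None:
    pd.DataFrame(
        {
            "time_min": series.times,
            "mean_ug_ml": series.means,
            "std_ug_ml": series.stds,
            "n_pixels": series.n_pixels,
        }
    ).to_csv(csv_path, index=False, float_format="%.10g")
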