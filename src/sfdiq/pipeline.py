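"""Pipeline configuration and the end-to-end run.

A single YAML file drives the full chain
demodulate -> calibrate -> fit optical properties -> correct fluorescence
-> kinetics.  The configuration is validated up front (unknown keys are
rejected, all input paths must exist) so a run fails fast, before any
stage writes output; a per-pixel failure inside a stage never aborts the
run — bad pixels propagate as masked values.

Every output directory receives a ``provenance.json`` carrying the SHA-256
of the configuration, so any artifact on disk can be traced to the exact
configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import io as sfio
from .calibrate import ReferencePhantom, calibrate_reflectance
from .core_model import OpticalProperties
from .demod import demodulate
from .fluor import correct_fluorescence, correction_factor, subtract_autofluorescence, to_concentration
from .invert import fit_optical_properties
from .kinetics import DEFAULT_PLATEAU_THRESHOLD, RegionOfInterest, percent_change, release_curve

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "output_dir", "n", "binning", "full_scale", "ref_mode",
    "plateau_threshold", "reflectance", "fluorescence", "roi",
}
_REFL_KEYS = {"sample_stack", "sample_meta", "reference_stack", "reference_meta", "reference_props"}
_FLUOR_KEYS = {"excitation_nm", "emission_nm", "calibration", "background", "frames"}
_FRAME_KEYS = {"time_min", "raw", "dark"}


def _reject_unknown(d, allowed, where):
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown configuration key(s) {sorted(unknown)} in {where}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for schema)."""

    output_dir: Path
    reflectance: dict
    n: float = 1.4
    binning: int = 1
    full_scale: float = 2**16 - 1
    ref_mode: str = "pixel"
    plateau_threshold: float = DEFAULT_PLATEAU_THRESHOLD
    fluorescence: dict | None = None
    roi: Path | None = None
    source_text: str = field(default="", repr=False)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=".", source_text: str = "") -> "PipelineConfig":
        base = Path(base_dir)
        _reject_unknown(raw, _TOP_KEYS, "top level")
        if "output_dir" not in raw or "reflectance" not in raw:
            raise ValueError("configuration requires 'output_dir' and 'reflectance'")
        refl = dict(raw["reflectance"])
        _reject_unknown(refl, _REFL_KEYS, "reflectance")
        missing = _REFL_KEYS - set(refl)
        if missing:
            raise ValueError(f"reflectance section is missing {sorted(missing)}")
        refl = {k: base / v for k, v in refl.items()}
        fluor = None
        if raw.get("fluorescence") is not None:
            fluor = dict(raw["fluorescence"])
            _reject_unknown(fluor, _FLUOR_KEYS, "fluorescence")
            for req in ("excitation_nm", "emission_nm", "calibration", "frames"):
                if req not in fluor:
                    raise ValueError(f"fluorescence section is missing {req!r}")
            fluor["calibration"] = base / fluor["calibration"]
            frames = []
            for fr in fluor["frames"]:
                _reject_unknown(fr, _FRAME_KEYS, "fluorescence frame")
                frames.append({"time_min": float(fr["time_min"]), "raw": base / fr["raw"],
                               "dark": (base / fr["dark"]) if fr.get("dark") else None})
            fluor["frames"] = sorted(frames, key=lambda f: f["time_min"])
            bg = fluor.get("background")
            if isinstance(bg, str):
                fluor["background"] = base / bg
        cfg = cls(
            output_dir=base / raw["output_dir"],
            reflectance=refl,
            n=float(raw.get("n", 1.4)),
            binning=int(raw.get("binning", 1)),
            full_scale=float(raw.get("full_scale", 2**16 - 1)),
            ref_mode=str(raw.get("ref_mode", "pixel")),
            plateau_threshold=float(raw.get("plateau_threshold", DEFAULT_PLATEAU_THRESHOLD)),
            fluorescence=fluor,
            roi=(base / raw["roi"]) if raw.get("roi") else None,
            source_text=source_text,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(raw, base_dir=Path(path).parent, source_text=text)

    def validate(self) -> None:
        if self.ref_mode not in ("pixel", "mean"):
            raise ValueError(f"ref_mode must be 'pixel' or 'mean', got {self.ref_mode!r}")
        if self.binning < 1:
            raise ValueError("binning must be >= 1")
        for key, path in self.reflectance.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input for reflectance.{key}: {path}")
        if self.fluorescence:
            if not Path(self.fluorescence["calibration"]).exists():
                raise FileNotFoundError(f"missing fluorescence calibration: {self.fluorescence['calibration']}")
            for fr in self.fluorescence["frames"]:
                if not Path(fr["raw"]).exists():
                    raise FileNotFoundError(f"missing fluorescence frame: {fr['raw']}")
                if fr["dark"] is not None and not Path(fr["dark"]).exists():
                    raise FileNotFoundError(f"missing dark frame: {fr['dark']}")
            bg = self.fluorescence.get("background")
            if isinstance(bg, Path) and not bg.exists():
                raise FileNotFoundError(f"missing background frame: {bg}")
        if self.roi is not None and not Path(self.roi).exists():
            raise FileNotFoundError(f"missing ROI file: {self.roi}")

    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode() or repr(self).encode()).hexdigest()


def _pool(frame: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a 2-D frame onto the binned fitting grid."""
    if factor == 1:
        return frame
    nr, nc = frame.shape
    rr, cc = (nr // factor) * factor, (nc // factor) * factor
    return frame[:rr, :cc].reshape(rr // factor, factor, cc // factor, factor).mean(axis=(1, 3))


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the full pipeline; returns a summary dict.

    Stages: demodulate (sample + reference) -> calibrate -> fit optical
    properties; then, when a fluorescence section is configured: X_1D
    correction -> autofluorescence subtraction -> concentration maps ->
    ROI kinetics.
    """
    stages = ["demodulate", "calibrate", "fit-op"]
    if config.fluorescence:
        stages += ["correct-fluor"]
        if config.roi is not None:
            stages += ["kinetics"]
    if dry_run:
        for s in stages:
            print(f"[dry-run] would run stage: {s}")
        return {"stages": stages, "dry_run": True}

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_sha256": config.config_hash(), "stages": stages}

    logger.info("stage demodulate")
    sample = sfio.load_stack(config.reflectance["sample_stack"], config.reflectance["sample_meta"])
    reference = sfio.load_stack(config.reflectance["reference_stack"], config.reflectance["reference_meta"])
    dem_s = demodulate(sample, full_scale=config.full_scale)
    dem_r = demodulate(reference, full_scale=config.full_scale)
    sfio.save_demodulated(dem_s, out / "demod_sample")
    sfio.save_demodulated(dem_r, out / "demod_reference")

    logger.info("stage calibrate")
    props = sfio.load_reference_props(config.reflectance["reference_props"])
    phantom = ReferencePhantom(props_by_wavelength=props, demod=dem_r)
    rd = calibrate_reflectance(dem_s, phantom, ref_mode=config.ref_mode)
    sfio.save_calibrated(rd, out / "calibrated")

    logger.info("stage fit-op (binning=%d)", config.binning)
    opmap = fit_optical_properties(rd, n=config.n, binning=config.binning)
    sfio.save_property_map(opmap, out / "optical_properties")

    summary = {
        "convergence_rate": opmap.convergence_rate(),
        "stages": stages,
        "config_sha256": provenance["config_sha256"],
    }

    if config.fluorescence:
        logger.info("stage correct-fluor")
        fl = config.fluorescence
        centers = [b.center_nm for b in opmap.wavelengths]
        try:
            ex_i = centers.index(float(fl["excitation_nm"]))
            em_i = centers.index(float(fl["emission_nm"]))
        except ValueError:
            raise ValueError(
                f"fluorescence wavelengths {fl['excitation_nm']}/{fl['emission_nm']} nm "
                f"not among fitted wavelengths {centers}"
            ) from None
        cal = sfio.load_calibration(fl["calibration"])
        rp = cal.ref_props
        ref_ex = OpticalProperties(rp["ex"]["mua_cm1"], rp["ex"]["musp_cm1"], rp["ex"].get("n", config.n))
        ref_em = OpticalProperties(rp["em"]["mua_cm1"], rp["em"]["musp_cm1"], rp["em"].get("n", config.n))
        x1d = correction_factor(
            opmap.mua[ex_i], opmap.musp[ex_i], opmap.mua[em_i], opmap.musp[em_i], ref_ex, ref_em
        )
        fdir = out / "fluor"
        fdir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(fdir / "x1d.tiff", x1d.astype(np.float32))

        bg = fl.get("background")
        if bg is None:
            background = 0.0
        elif isinstance(bg, Path):
            # a pre-injection RAW frame: dark-subtract and correct like the rest
            raw_bg = _pool(tifffile.imread(bg).astype(float), config.binning)
            first_dark = fl["frames"][0]["dark"]
            dark_bg = _pool(tifffile.imread(first_dark).astype(float), config.binning) if first_dark else 0.0
            background = correct_fluorescence(raw_bg, dark_bg, x1d)
        else:
            background = float(bg)

        times, conc_maps, fractions = [], [], []
        for fr in fl["frames"]:
            raw = _pool(tifffile.imread(fr["raw"]).astype(float), config.binning)
            dark = _pool(tifffile.imread(fr["dark"]).astype(float), config.binning) if fr["dark"] else 0.0
            f_corr = correct_fluorescence(raw, dark, x1d)
            f_signal, frac = subtract_autofluorescence(f_corr, background)
            conc = to_concentration(f_signal, cal)
            t = fr["time_min"]
            tifffile.imwrite(fdir / f"conc_t{t:07.2f}.tiff", conc.astype(np.float32))
            times.append(t)
            conc_maps.append(conc)
            fractions.append(frac)
        summary["autofluorescence_fraction"] = fractions

        if config.roi is not None:
            logger.info("stage kinetics")
            roi = sfio.load_roi(config.roi)
            if roi.vertices is not None and config.binning > 1:
                roi = RegionOfInterest(roi.name, vertices=roi.vertices / config.binning)
            if len(times) >= 2:
                series, plateau = release_curve(times, conc_maps, roi, config.plateau_threshold)
                sfio.save_kinetics(series, out / "kinetics.csv")
                summary["plateau_time_min"] = plateau
                summary["roi_means_ug_ml"] = [float(v) for v in series.means]
                if series.means[0] > 0:
                    summary["percent_change_first_last"] = percent_change(series.means[0], series.means[-1])
            else:
                from .kinetics import roi_stats

                mean, std, npix = roi_stats(conc_maps[0], roi)
                summary["roi_means_ug_ml"] = [mean]

    sfio._write_json(out / "provenance.json", provenance)
    sfio._write_json(out / "summary.json", _jsonable(summary))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
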