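"""One-shot QC orchestration: run every analyzer whose inputs exist and
compare measurements against first-order design predictions.

The report pairs each measured quantity with its prediction when one
exists (measured PSF vs diffraction limit, measured field diagonal vs
predicted FOV) and attaches a pass/warn flag at a configurable tolerance.
Warn flags never change the exit status; only hard per-stage errors do,
and an error in one stage does not stop the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__, field as field_cal, io as qio, models, optics, psf

logger = logging.getLogger("scopeqc")

__all__ = ["QcConfig", "run_qc", "optics_report"]

_TOP_LEVEL_KEYS = ("optics", "inputs", "analysis", "seed")
_INPUT_KEYS = ("grid_image", "bath_image", "bead_volume", "pockels_scan", "gdd_scan")
_ANALYSIS_KEYS = (
    "grid_pitch_um",
    "bath_pixel_size_um",
    "bath_roi_um",
    "bead_pixel_size_um",
    "bead_z_step_um",
    "psf_threshold_sd",
    "psf_isolation_radius_um",
    "expected_radial_fwhm_um",
    "expected_axial_fwhm_um",
    "tolerance_percent",
    "saturation",
)

_ANALYSIS_DEFAULTS: dict[str, Any] = {
    "grid_pitch_um": 100.0,
    "bath_pixel_size_um": 2.77,
    "bath_roi_um": 700.0,
    "bead_pixel_size_um": 0.2,
    "bead_z_step_um": 0.5,
    "psf_threshold_sd": 8.0,
    "psf_isolation_radius_um": 5.0,
    "expected_radial_fwhm_um": 0.8,
    "expected_axial_fwhm_um": 5.0,
    "tolerance_percent": 10.0,
    "saturation": 32768.0,
}


@dataclass(frozen=True)
class QcConfig:
    """Validated QC-run configuration (schema errors name the offending key)."""

    optics: dict[str, float] | None = None
    inputs: dict[str, str] = dc_field(default_factory=dict)
    analysis: dict[str, Any] = dc_field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict) -> "QcConfig":
        unknown = set(cfg) - set(_TOP_LEVEL_KEYS)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        op = cfg.get("optics")
        if op is not None:
            bad = set(op) - set(qio.OPTICS_CONFIG_KEYS)
            if bad:
                raise ValueError(f"unknown optics keys {sorted(bad)}")
            for key in qio.OPTICS_CONFIG_KEYS:
                if key not in op:
                    raise ValueError(f"missing optics key '{key}'")
        inputs = cfg.get("inputs", {})
        bad = set(inputs) - set(_INPUT_KEYS)
        if bad:
            raise ValueError(f"unknown input keys {sorted(bad)}")
        analysis = dict(_ANALYSIS_DEFAULTS)
        extra = cfg.get("analysis", {})
        bad = set(extra) - set(_ANALYSIS_KEYS)
        if bad:
            raise ValueError(f"unknown analysis keys {sorted(bad)}")
        analysis.update(extra)
        return cls(
            optics=op, inputs=inputs, analysis=analysis, seed=int(cfg.get("seed", 0))
        )

    def to_dict(self) -> dict:
        return {
            "optics": self.optics,
            "inputs": self.inputs,
            "analysis": self.analysis,
            "seed": self.seed,
        }

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def optics_report(cfg: dict[str, float]) -> dict[str, Any]:
    """Design predictions from a flat optical-train config (units explicit)."""
    relay = optics.RelaySpec(
        scan_focal_length_mm=cfg["scan_focal_length_mm"],
        tube_focal_length_mm=cfg["tube_focal_length_mm"],
        scanner_half_angle_deg=cfg["scanner_half_angle_deg"],
        beam_fill_fraction=cfg["beam_fill_fraction"],
    )
    objective = optics.ObjectiveSpec(
        focal_length_mm=cfg["objective_focal_length_mm"],
        na=cfg["objective_na"],
        immersion_index=cfg["immersion_index"],
    )
    na_eff = optics.effective_excitation_na(objective, relay)
    limits = optics.diffraction_limits(
        cfg["wavelength_nm"], na_eff, cfg["immersion_index"]
    )
    coll = optics.collection_fraction(objective.na, objective.immersion_index)
    return {
        "relay_magnification": {"value": optics.relay_magnification(relay), "units": ""},
        "pupil_scan_half_angle": {
            "value": optics.pupil_scan_half_angle(relay),
            "units": "deg",
        },
        "predicted_fov_diameter": {
            "value": optics.predicted_fov_diameter(relay, objective),
            "units": "mm",
        },
        "effective_excitation_na": {"value": na_eff, "units": ""},
        "diffraction_radial_fwhm": {"value": limits.radial_fwhm_nm, "units": "nm"},
        "diffraction_axial_fwhm": {"value": limits.axial_fwhm_um, "units": "um"},
        "collection_half_angle": {"value": coll.half_angle_deg, "units": "deg"},
        "collection_sphere_fraction": {"value": coll.sphere_fraction, "units": ""},
    }


def _compare(measured: float, predicted: float, tol_percent: float) -> dict:
    dev = 100.0 * abs(measured - predicted) / abs(predicted)
    return {
        "measured": measured,
        "predicted": predicted,
        "deviation_percent": dev,
        "status": "pass" if dev <= tol_percent else "warn",
    }


def run_qc(config: QcConfig | dict, out_dir: str | Path | None = None) -> dict:
    """Execute optics predictions plus every analyzer whose input is present.

    Returns the QC report as a JSON-serializable dict; if ``out_dir`` is
    given, writes ``qc_report.json``, a human-readable ``qc_report.txt``
    and the resolved config next to it. Per-stage failures are recorded
    under ``errors`` without aborting the remaining stages.
    """
    if isinstance(config, dict):
        config = QcConfig.from_dict(config)
    ana = config.analysis
    tol = float(ana["tolerance_percent"])
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "errors": {},
        "comparisons": {},
    }

    predictions = None
    if config.optics is not None:
        try:
            predictions = optics_report(config.optics)
            report["optics"] = predictions
            logger.info("optics predictions computed (%d items)", len(predictions))
        except Exception as exc:  # noqa: BLE001 - per-stage isolation
            report["errors"]["optics"] = str(exc)

    def stage(name):
        def deco(fn):
            path = config.inputs.get(name)
            if path is None:
                return
            try:
                fn(path)
                logger.info("stage %s completed", name)
            except Exception as exc:  # noqa: BLE001 - per-stage isolation
                logger.error("stage %s failed: %s", name, exc)
                report["errors"][name] = str(exc)

        return deco

    @stage("grid_image")
    def _grid(path):
        img = qio.read_image(path)
        smap = field_cal.grid_scale_map(img, float(ana["grid_pitch_um"]))
        dist = field_cal.distortion_metric(smap)
        fov = field_cal.fov_summary(smap)
        report["field"] = {
            "scale_mean_um_per_px": {"value": smap.scale_mean, "units": "um/px"},
            "scale_sd_um_per_px": {"value": smap.scale_sd, "units": "um/px"},
            "distortion_center_vs_edge": {"value": dist, "units": "%"},
            "n_cells": {"value": len(smap.cells), "units": ""},
            "fov_diagonal_mm": {"value": fov.diagonal_mm, "units": "mm"},
            "fov_area_mm2": {"value": fov.area_mm2, "units": "mm^2"},
            "flags": list(smap.flags),
        }
        if predictions is not None:
            report["comparisons"]["fov_diagonal_vs_predicted_diameter"] = _compare(
                fov.diagonal_mm, predictions["predicted_fov_diameter"]["value"], tol
            )

    @stage("bath_image")
    def _bath(path):
        img = qio.read_image(path, float(ana["bath_pixel_size_um"]))
        res = field_cal.uniformity_stats(
            img,
            float(ana["bath_roi_um"]),
            float(ana["bath_pixel_size_um"]),
            saturation=float(ana["saturation"]),
        )
        report["uniformity"] = {
            "roi_um": {"value": list(res.roi_um), "units": "um"},
            "mean": {"value": res.mean_counts, "units": "counts"},
            "sd": {"value": res.sd_counts, "units": "counts"},
            "percent_deviation": {"value": res.percent_deviation, "units": "%"},
            "n_saturated_excluded": {"value": res.n_saturated_excluded, "units": ""},
            "flags": list(res.flags),
        }

    @stage("bead_volume")
    def _beads(path):
        vol = psf.ImageVolume(
            qio.read_image(path, float(ana["bead_pixel_size_um"])),
            float(ana["bead_pixel_size_um"]),
            float(ana["bead_z_step_um"]),
        )
        res = psf.psf_report(
            vol,
            threshold_sd=float(ana["psf_threshold_sd"]),
            isolation_radius_um=float(ana["psf_isolation_radius_um"]),
            expected_radial_fwhm_um=float(ana["expected_radial_fwhm_um"]),
            expected_axial_fwhm_um=float(ana["expected_axial_fwhm_um"]),
        )
        logger.info(
            "psf: %d beads measured (radial %.0f nm, axial %.2f um)",
            res.n_beads,
            res.radial_fwhm_mean_nm,
            res.axial_fwhm_mean_um,
        )
        report["psf"] = {
            "radial_fwhm": {"value": res.radial_fwhm_mean_nm, "units": "nm"},
            "radial_fwhm_sd": {"value": res.radial_fwhm_sd_um * 1e3, "units": "nm"},
            "axial_fwhm": {"value": res.axial_fwhm_mean_um, "units": "um"},
            "axial_fwhm_sd": {"value": res.axial_fwhm_sd_um, "units": "um"},
            "n_beads": {"value": res.n_beads, "units": ""},
            "flags": list(res.flags),
        }
        if predictions is not None:
            report["comparisons"]["radial_fwhm_vs_diffraction"] = _compare(
                res.radial_fwhm_mean_nm,
                predictions["diffraction_radial_fwhm"]["value"],
                tol,
            )
            report["comparisons"]["axial_fwhm_vs_diffraction"] = _compare(
                res.axial_fwhm_mean_um,
                predictions["diffraction_axial_fwhm"]["value"],
                tol,
            )

    @stage("pockels_scan")
    def _pockels(path):
        fit = models.fit_pockels(qio.read_scan(path, "pockels"))
        p = fit.params
        report["pockels_fit"] = {
            "p0": {"value": p.p0_mw, "stderr": fit.stderr["p0_mw"], "units": "mW"},
            "v0": {"value": p.v0_v, "stderr": fit.stderr["v0_v"], "units": "V"},
            "phase": {
                "value": p.phase_rad,
                "stderr": fit.stderr["phase_rad"],
                "units": "rad",
            },
            "rss": {"value": fit.rss, "units": "mW^2"},
            "n_points": {"value": fit.n_points, "units": ""},
        }

    @stage("gdd_scan")
    def _gdd(path):
        fit = models.fit_dispersion_scan(qio.read_scan(path, "gdd"))
        p = fit.params
        report["gdd_fit"] = {
            "i0": {"value": p.i0, "stderr": fit.stderr["i0"], "units": "au"},
            "phi0": {
                "value": p.phi0_fs2,
                "stderr": fit.stderr["phi0_fs2"],
                "units": "fs^2",
            },
            "delta_tau": {
                "value": p.delta_tau_fs,
                "stderr": fit.stderr["delta_tau_fs"],
                "units": "fs",
            },
            "rss": {"value": fit.rss, "units": "au^2"},
            "n_points": {"value": fit.n_points, "units": ""},
            "flags": list(fit.flags),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        qio.write_json(out_dir / "qc_report.json", report)
        qio.write_json(out_dir / "qc_config.json", config.to_dict())
        (out_dir / "qc_report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Human-readable summary of a QC report."""
    lines = [
        f"scopeqc QC report (version {report['version']}, "
        f"config {report['config_hash']})",
        "",
    ]
    for section, content in report.items():
        if section in ("version", "config_hash", "seed", "errors", "comparisons"):
            continue
        lines.append(f"[{section}]")
        for name, item in content.items():
            if isinstance(item, dict) and "value" in item:
                err = f" ± {item['stderr']:.4g}" if "stderr" in item else ""
                val = item["value"]
                val_s = f"{val:.6g}" if isinstance(val, (int, float)) else str(val)
                lines.append(f"  {name} = {val_s}{err} {item.get('units', '')}")
            else:
                lines.append(f"  {name} = {item}")
        lines.append("")
    if report["comparisons"]:
        lines.append("[comparisons]")
        for name, c in report["comparisons"].items():
            lines.append(
                f"  {name}: measured {c['measured']:.4g} vs predicted "
                f"{c['predicted']:.4g} ({c['deviation_percent']:.1f}% off) "
                f"-> {c['status'].upper()}"
            )
        lines.append("")
    if report["errors"]:
        lines.append("[errors]")
        for stage_name, msg in report["errors"].items():
            lines.append(f"  {stage_name}: {msg}")
        lines.append("")
    return "\n".join(lines)
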