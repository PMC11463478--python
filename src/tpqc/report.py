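"""QC orchestration: run configured analyses and emit one JSON report.

A config (dict, or YAML/JSON file via the CLI) selects which analyses to
run — first-order optics, Pockels sweep fit, dispersion sweep fit,
calibration-grid scale map, bath uniformity, bead PSF — and the report
juxtaposes measured resolution and field size against the paraxial
predictions.  One failing analysis does not abort the others; its error is
recorded and the exit status distinguishes full success (0), partial
success (3), and total failure (4).
"""

from __future__ import annotations

import datetime
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .errors import ConfigError, TpqcError
from .dispersion import GddSweep, fit_gdd_sweep
from .field import (
    BathImage,
    CalibrationGridImage,
    detect_grid_lattice,
    local_scale_map,
    scale_summary,
    uniformity_stats,
)
from .optics import ObjectiveSpec, ScanRelaySpec, design_summary
from .pockels import PowerSweep, dynamic_range, fit_transmission
from .psf import BeadVolume, psf_report

__all__ = ["QcReport", "run_qc", "write_report", "load_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_PARTIAL = 3
EXIT_ALL_FAILED = 4


@dataclass
class QcReport:
    """Aggregated QC results: one block per analysis plus comparisons."""

    schema_version: str = SCHEMA_VERSION
    tool_version: str = __version__
    timestamp: str = ""
    config: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    @property
    def exit_status(self) -> int:
        if self.errors and not self.blocks:
            return EXIT_ALL_FAILED
        if self.errors:
            return EXIT_PARTIAL
        return EXIT_OK

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
            "config": self.config,
            "blocks": self.blocks,
            "comparisons": self.comparisons,
            "errors": self.errors,
            "timings_s": self.timings_s,
        }


def _run_optics(cfg: dict) -> dict:
    objective = ObjectiveSpec(
        focal_length_mm=cfg.get("objective_focal_mm", 12.5),
        numerical_aperture=cfg.get("objective_na", 0.8),
        immersion_index=cfg.get("immersion_index", 1.33),
        back_aperture_diameter_mm=cfg.get("back_aperture_mm", 20.0),
    )
    relay = ScanRelaySpec(
        scan_lens_focal_mm=cfg.get("scan_lens_focal_mm", 100.0),
        tube_lens_focal_mm=cfg.get("tube_lens_focal_mm", 375.0),
        scan_half_angle_deg=cfg.get("scan_half_angle_deg", 10.0),
        beam_diameter_at_pupil_mm=cfg.get("beam_diameter_at_pupil_mm", 17.5),
    )
    return design_summary(objective, relay, cfg.get("wavelength_nm", 920.0)).to_dict()


def _run_pockels(cfg: dict, base: Path) -> dict:
    sweep = PowerSweep.from_csv(base / cfg["sweep_csv"])
    fit = fit_transmission(sweep)
    out = fit.to_dict()
    if "v_min" in cfg and "v_max" in cfg:
        ratio, v_hi, v_lo = dynamic_range(fit, cfg["v_min"], cfg["v_max"])
        out["window_dynamic_range"] = {"ratio": ratio, "v_at_max": v_hi, "v_at_min": v_lo}
    return out


def _run_gdd(cfg: dict, base: Path) -> dict:
    sweep = GddSweep.from_csv(base / cfg["sweep_csv"])
    return fit_gdd_sweep(sweep).to_dict()


def _run_grid(cfg: dict, base: Path) -> dict:
    raster = tifffile.imread(base / cfg["image_tiff"])
    image = CalibrationGridImage(
        raster=raster,
        grid_pitch_um=cfg.get("pitch_um", 100.0),
        nominal_scale_um_per_px=cfg.get("um_per_px"),
    )
    lattice = detect_grid_lattice(image)
    smap = local_scale_map(lattice, image.grid_pitch_um)
    summary = scale_summary(
        smap, image.raster.shape, cfg.get("center_fraction", 0.33)
    )
    out = summary.to_dict()
    out["n_cells"] = int(smap.scale_um_per_px.size)
    return out


def _run_bath(cfg: dict, base: Path) -> dict:
    raster = tifffile.imread(base / cfg["image_tiff"])
    image = BathImage(raster=raster, scale_um_per_px=cfg["um_per_px"])
    report = uniformity_stats(image, roi_um=cfg.get("roi_um", 700.0))
    out = report.to_dict()
    # profiles are bulky; keep only their lengths in the report
    for key in ("row_profile", "row_profile_sd", "col_profile", "col_profile_sd"):
        out[key + "_len"] = len(out.pop(key))
    return out


def _run_psf(cfg: dict, base: Path) -> dict:
    stack = tifffile.imread(base / cfg["image_tiff"])
    volume = BeadVolume(
        stack=stack,
        voxel_xy_um=cfg["dxy_um"],
        voxel_z_um=cfg["dz_um"],
        bead_diameter_um=cfg.get("bead_diameter_um", 0.2),
    )
    estimate = psf_report(
        volume,
        min_separation_um=cfg.get("min_separation_um", 10.8),
        threshold_sigmas=cfg.get("threshold_sigmas", 5.0),
    )
    return estimate.to_dict()


_RUNNERS = {
    "pockels": _run_pockels,
    "gdd": _run_gdd,
    "grid": _run_grid,
    "bath": _run_bath,
    "psf": _run_psf,
}


def run_qc(
    config: dict, base_dir: str | Path = ".", timestamp: str | None = None
) -> QcReport:
    """Execute every analysis named in ``config`` and aggregate the results.

    ``config`` maps analysis names ('optics', 'pockels', 'gdd', 'grid',
    'bath', 'psf') to their parameter blocks.  Failures are isolated per
    block.  ``timestamp`` may be pinned for reproducible reports.
    """
    if not isinstance(config, dict) or not config:
        raise ConfigError("config must be a non-empty mapping of analysis blocks")
    unknown = set(config) - (set(_RUNNERS) | {"optics"})
    if unknown:
        raise ConfigError(f"unknown analysis blocks: {sorted(unknown)}")
    base = Path(base_dir)
    report = QcReport(
        timestamp=timestamp
        or datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        config=config,
    )
    for name, cfg in config.items():
        t0 = time.perf_counter()
        try:
            if name == "optics":
                report.blocks[name] = _run_optics(cfg or {})
            else:
                report.blocks[name] = _RUNNERS[name](cfg or {}, base)
        except (TpqcError, OSError, KeyError, ValueError) as exc:
            report.errors[name] = f"{type(exc).__name__}: {exc}"
        report.timings_s[name] = round(time.perf_counter() - t0, 4)

    _add_comparisons(report)
    return report


def _add_comparisons(report: QcReport) -> None:
    """Measured-vs-predicted ratios where both sides are available."""
    optics = report.blocks.get("optics")
    if not optics:
        return
    psf = report.blocks.get("psf")
    if psf:
        report.comparisons["radial_fwhm_measured_over_limit"] = (
            psf["dr_mean_nm"] / (optics["radial_limit_um"] * 1000.0)
        )
        report.comparisons["axial_fwhm_measured_over_limit"] = (
            psf["dz_mean_um"] / optics["axial_limit_um"]
        )
    grid = report.blocks.get("grid")
    if grid:
        report.comparisons["fov_diagonal_measured_over_predicted"] = (
            grid["fov_diagonal_mm"] / (optics["fov_diameter_mm"] * np.sqrt(2.0))
        )


def write_report(report: QcReport, path: str | Path) -> None:
    """Serialise to JSON with stable key order; absent blocks are omitted."""
    payload = report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def load_report(path: str | Path) -> QcReport:
    """Load a report, rejecting unknown major schema versions."""
    with open(path) as fh:
        payload = json.load(fh)
    major = str(payload.get("schema_version", "")).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ConfigError(
            f"unsupported report schema version {payload.get('schema_version')}"
        )
    return QcReport(
        schema_version=payload["schema_version"],
        tool_version=payload.get("tool_version", ""),
        timestamp=payload.get("timestamp", ""),
        config=payload.get("config", {}),
        blocks=payload.get("blocks", {}),
        comparisons=payload.get("comparisons", {}),
        errors=payload.get("errors", {}),
        timings_s=payload.get("timings_s", {}),
    )
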