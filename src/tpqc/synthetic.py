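"""Seeded synthetic instrument data for desk-top testing of the QC pipeline.

Every generator is a pure function of (parameters, seed): the same call
produces a bit-identical dataset, and each dataset is paired with a
:class:`GroundTruth` record sufficient to recompute any reported statistic
by brute force.

Default parameters describe a realistic mid-size two-photon system: a
~1.4 mm field imaged at 2.77 um/px with a 100 um calibration grid and mild
barrel distortion, a Gaussian-vignetted Fluorescein bath whose central
700x700 um region deviates ~13% (SD/mean) from flat, 0.2 um bead phantoms
blurred by an anisotropic Gaussian two-photon PSF (FWHM 760 nm radial,
5.4 um axial) with Poisson noise, a sin^2 Pockels transmission sweep and a
Gaussian-pulse dispersion sweep (system dispersion ~20200 fs^2, pulse FWHM
~150 fs).

Noise models: additive Gaussian for the detector-dominated 1-D sweeps and
2-D rasters, Poisson for the photon-limited bead volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dispersion import GddSweep, fluorescence_model
from .errors import CapacityError, InvalidParameterError
from .field import BathImage, CalibrationGridImage
from .pockels import PowerSweep, transmission_model
from .psf import FWHM_PER_SIGMA, BeadVolume

__all__ = [
    "GroundTruth",
    "gen_grid_image",
    "gen_bath_image",
    "gen_bead_volume",
    "gen_pockels_sweep",
    "gen_gdd_sweep",
]

#: Barrel coefficient (px^-2) reproducing a centre-to-edge scale deviation
#: of ~0.1 um/px (~4% of S) on a 512 px field at 2.77 um/px.
DEFAULT_BARREL_K: float = 5e-7

#: Vignette width (um) whose closed-form SD/mean over a central
#: 700x700 um ROI is 13.0%.
DEFAULT_VIGNETTE_SIGMA_UM: float = 440.0


@dataclass
class GroundTruth:
    """Generator name, full parameter set, and seed for one dataset."""

    generator: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=float)


def _invert_radial_warp(r_warped: np.ndarray, k: float, iters: int = 30) -> np.ndarray:
    """Solve r (1 + k r^2) = r_warped for r by Newton iteration."""
    r = r_warped.copy()
    for _ in range(iters):
        f = r + k * r**3 - r_warped
        r = r - f / (1.0 + 3.0 * k * r**2)
    return r


def gen_grid_image(
    scale_um_per_px: float = 2.77,
    pitch_um: float = 100.0,
    size_px: tuple[int, int] = (540, 540),
    line_width_um: float = 6.0,
    barrel_k: float = 0.0,
    noise_sd: float = 0.0,
    background: float = 1.0,
    line_depth: float = 0.8,
    seed: int = 0,
) -> tuple[CalibrationGridImage, GroundTruth]:
    """Dark grid lines on a bright background, optionally barrel-warped.

    The radial warp r' = r (1 + k r^2) about the image centre is applied to
    the line coordinates (a pixel at warped radius r' shows the ideal-space
    content at radius r).  Lines are anti-aliased by sub-pixel coverage.
    """
    if scale_um_per_px <= 0 or pitch_um <= 0 or min(size_px) <= 0:
        raise InvalidParameterError("scale, pitch and size must be positive")
    pitch_px = pitch_um / scale_um_per_px
    if pitch_px < 3:
        raise InvalidParameterError("pitch below 3 px at this scale")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = size_px
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    y, x = np.mgrid[0:n_rows, 0:n_cols]
    py, px = y - cy, x - cx
    if barrel_k != 0.0:
        r_warped = np.hypot(py, px)
        r_ideal = _invert_radial_warp(r_warped, barrel_k)
        ratio = np.where(r_warped > 0, r_ideal / r_warped, 1.0)
        uy, ux = py * ratio, px * ratio
    else:
        uy, ux = py, px
    half_w = line_width_um / scale_um_per_px / 2.0

    def coverage(u: np.ndarray) -> np.ndarray:
        d = np.abs((u + pitch_px / 2.0) % pitch_px - pitch_px / 2.0)
        return np.clip(half_w + 0.5 - d, 0.0, 1.0)

    cov = np.maximum(coverage(ux), coverage(uy))
    raster = background * (1.0 - line_depth * cov)
    if noise_sd > 0:
        raster = raster + rng.normal(0.0, noise_sd, raster.shape)
    raster = np.clip(raster, 0.0, None)

    # ideal-space line coordinates (px, relative to centre) hosting lines
    n_lines_x = int(cx // pitch_px)
    n_lines_y = int(cy // pitch_px)
    lines_x = np.arange(-n_lines_x, n_lines_x + 1) * pitch_px
    lines_y = np.arange(-n_lines_y, n_lines_y + 1) * pitch_px
    truth = GroundTruth(
        generator="grid",
        params={
            "scale_um_per_px": scale_um_per_px,
            "pitch_um": pitch_um,
            "pitch_px": pitch_px,
            "size_px": list(size_px),
            "line_width_um": line_width_um,
            "barrel_k": barrel_k,
            "noise_sd": noise_sd,
            "background": background,
            "line_depth": line_depth,
            "lines_x_ideal_px": lines_x.tolist(),
            "lines_y_ideal_px": lines_y.tolist(),
        },
        seed=seed,
    )
    image = CalibrationGridImage(
        raster=raster, grid_pitch_um=pitch_um, nominal_scale_um_per_px=scale_um_per_px
    )
    return image, truth


def gen_bath_image(
    size_px: tuple[int, int] = (512, 512),
    scale_um_per_px: float = 2.77,
    vignette_sigma_um: float = DEFAULT_VIGNETTE_SIGMA_UM,
    level: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BathImage, GroundTruth]:
    """Uniform bath with a centred Gaussian vignette plus Gaussian noise."""
    if min(size_px) <= 0 or scale_um_per_px <= 0 or vignette_sigma_um <= 0 or level <= 0:
        raise InvalidParameterError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = size_px
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    y, x = np.mgrid[0:n_rows, 0:n_cols]
    r2_um = ((y - cy) ** 2 + (x - cx) ** 2) * scale_um_per_px**2
    raster = level * np.exp(-r2_um / (2.0 * vignette_sigma_um**2))
    if noise_sd > 0:
        raster = raster + rng.normal(0.0, noise_sd, raster.shape)
    raster = np.clip(raster, 0.0, None)
    truth = GroundTruth(
        generator="bath",
        params={
            "size_px": list(size_px),
            "scale_um_per_px": scale_um_per_px,
            "vignette_sigma_um": vignette_sigma_um,
            "level": level,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return BathImage(raster=raster, scale_um_per_px=scale_um_per_px), truth


def _amplitude_for_snr(peak_snr: float, background: float) -> float:
    """Peak amplitude A with Poisson noise such that A / sqrt(A + B) = SNR."""
    s2 = peak_snr**2
    return (s2 + np.sqrt(s2**2 + 4.0 * s2 * background)) / 2.0


def gen_bead_volume(
    n_beads: int = 38,
    fwhm_r_nm: float = 760.0,
    fwhm_z_um: float = 5.4,
    voxel_xy_um: float = 0.2,
    voxel_z_um: float = 1.0,
    size: tuple[int, int, int] = (50, 512, 512),
    peak_snr: float | None = 20.0,
    min_separation_um: float = 12.0,
    background: float = 10.0,
    amplitude: float | None = None,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[BeadVolume, GroundTruth]:
    """Sparse sub-resolution bead phantom blurred by a Gaussian PSF.

    The effective two-photon PSF is modelled directly as a separable
    anisotropic Gaussian (radial FWHM ``fwhm_r_nm``, axial ``fwhm_z_um``).
    Beads sit at uniformly random, non-overlapping, sub-voxel positions at
    least half an extraction window from every edge; constant background
    plus Poisson noise is scaled so the peak SNR (amplitude over shot noise
    at the peak) equals ``peak_snr``.  ``peak_snr=None`` disables noise.
    """
    if n_beads < 1 or fwhm_r_nm <= 0 or fwhm_z_um <= 0:
        raise InvalidParameterError("bead count and FWHMs must be positive")
    rng = np.random.default_rng(seed)
    nz, ny, nx = size
    sigma_r_px = fwhm_r_nm / 1000.0 / FWHM_PER_SIGMA / voxel_xy_um
    sigma_z_px = fwhm_z_um / FWHM_PER_SIGMA / voxel_z_um

    # keep beads at least half a default extraction window from the edges
    margin_z = 20.0 / 2.0 / voxel_z_um + 1
    margin_xy = 6.0 / 2.0 / voxel_xy_um + 1
    lo = np.array([margin_z, margin_xy, margin_xy])
    hi = np.array([nz - 1 - margin_z, ny - 1 - margin_xy, nx - 1 - margin_xy])
    if np.any(hi <= lo):
        raise CapacityError("volume too small for the edge margins")

    scale_um = np.array([voxel_z_um, voxel_xy_um, voxel_xy_um])
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n_beads:
        if tries >= max_tries:
            raise CapacityError(
                f"could not place {n_beads} beads at {min_separation_um} um "
                f"separation after {max_tries} draws"
            )
        tries += 1
        cand = lo + rng.random(3) * (hi - lo)
        ok = all(
            np.sum(((cand - p) * scale_um) ** 2) >= min_separation_um**2
            for p in positions
        )
        if ok:
            positions.append(cand)
    pos = np.array(positions)

    if amplitude is None:
        amplitude = (
            _amplitude_for_snr(peak_snr, background) if peak_snr is not None else 100.0
        )

    clean = np.full(size, float(background))
    reach = (int(np.ceil(4 * sigma_z_px)), int(np.ceil(4 * sigma_r_px)))
    for cz, cy, cx in pos:
        z0, z1 = max(int(cz) - reach[0], 0), min(int(cz) + reach[0] + 1, nz)
        y0, y1 = max(int(cy) - reach[1], 0), min(int(cy) + reach[1] + 1, ny)
        x0, x1 = max(int(cx) - reach[1], 0), min(int(cx) + reach[1] + 1, nx)
        zz = np.arange(z0, z1, dtype=float) - cz
        yy = np.arange(y0, y1, dtype=float) - cy
        xx = np.arange(x0, x1, dtype=float) - cx
        gz = np.exp(-(zz**2) / (2.0 * sigma_z_px**2))
        gy = np.exp(-(yy**2) / (2.0 * sigma_r_px**2))
        gx = np.exp(-(xx**2) / (2.0 * sigma_r_px**2))
        clean[z0:z1, y0:y1, x0:x1] += (
            amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    stack = rng.poisson(clean).astype(float) if peak_snr is not None else clean

    truth = GroundTruth(
        generator="beads",
        params={
            "n_beads": n_beads,
            "fwhm_r_nm": fwhm_r_nm,
            "fwhm_z_um": fwhm_z_um,
            "voxel_xy_um": voxel_xy_um,
            "voxel_z_um": voxel_z_um,
            "size": list(size),
            "peak_snr": peak_snr,
            "min_separation_um": min_separation_um,
            "background": background,
            "amplitude": amplitude,
            "positions_zyx_voxels": pos.tolist(),
        },
        seed=seed,
    )
    volume = BeadVolume(
        stack=stack, voxel_xy_um=voxel_xy_um, voxel_z_um=voxel_z_um, bead_diameter_um=0.2
    )
    return volume, truth


def gen_pockels_sweep(
    p0: float = 1.0,
    v0_V: float = 120.0,
    phase: float = 0.6,
    v_range: tuple[float, float] = (0.0, 240.0),
    n_points: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[PowerSweep, GroundTruth]:
    """sin^2 transmission sweep on an even voltage grid, clipped at 0."""
    if n_points < 6:
        raise InvalidParameterError("need at least 6 points")
    rng = np.random.default_rng(seed)
    v = np.linspace(v_range[0], v_range[1], n_points)
    p = np.asarray(transmission_model(v, p0, v0_V, phase), dtype=float)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, p.shape)
    p = np.clip(p, 0.0, None)
    truth = GroundTruth(
        generator="pockels",
        params={
            "p0": p0,
            "v0_V": v0_V,
            "phase": phase,
            "v_range": list(v_range),
            "n_points": n_points,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return PowerSweep(voltage=v, power=p, meta={"synthetic": True}), truth


def gen_gdd_sweep(
    i0: float = 1.0,
    gdd0_fs2: float = 20200.0,
    dtau_fs: float = 150.0,
    gdd_range: tuple[float, float] = (-30200.0, -10200.0),
    n_points: int = 60,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[GddSweep, GroundTruth]:
    """Dispersion sweep on an even grid of applied (negative) compensation.

    Noise is multiplicative Gaussian with fractional SD ``noise_frac``.
    """
    if n_points < 8:
        raise InvalidParameterError("need at least 8 points")
    rng = np.random.default_rng(seed)
    g = np.linspace(gdd_range[0], gdd_range[1], n_points)
    f = np.asarray(fluorescence_model(g, i0, gdd0_fs2, dtau_fs), dtype=float)
    if noise_frac > 0:
        f = f * (1.0 + rng.normal(0.0, noise_frac, f.shape))
    f = np.clip(f, 0.0, None)
    truth = GroundTruth(
        generator="gdd",
        params={
            "i0": i0,
            "gdd0_fs2": gdd0_fs2,
            "dtau_fs": dtau_fs,
            "gdd_range": list(gdd_range),
            "n_points": n_points,
            "noise_frac": noise_frac,
        },
        seed=seed,
    )
    return GddSweep(gdd_fs2=g, fluorescence_au=f, meta={"synthetic": True}), truth
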