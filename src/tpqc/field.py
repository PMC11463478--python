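"""Field-of-view scale mapping and illumination-uniformity statistics.

Two desk-top QC measurements of a laser-scanning microscope:

* a calibration grid of known pitch (typically 100 um) imaged across the
  field gives the local scale S (um/px) per grid cell, its spread, and the
  centre-vs-edge deviation that quantifies distortion of the scan field;
* a uniform fluorescent bath (e.g. Fluorescein) gives excitation/collection
  uniformity as intensity profiles and the SD/mean statistic over a central
  region of interest.

Grid analysis is axis-separable: each axis is reduced to its mean
projection, line positions are found by peak detection with 3-point
parabolic sub-pixel refinement, and adjacent line spacings yield per-cell
scales.  This is adequate for the mild (few percent) distortion of a
closely-mounted scanner pair; it is not a full 2-D distortion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import skew

from .errors import DetectionFailureError, InvalidParameterError

__all__ = [
    "CalibrationGridImage",
    "ScaleMap",
    "ScaleSummary",
    "BathImage",
    "UniformityReport",
    "detect_grid_lattice",
    "local_scale_map",
    "scale_summary",
    "uniformity_profiles",
    "uniformity_stats",
]


@dataclass
class CalibrationGridImage:
    """A single-plane image of a square calibration grid.

    raster is indexed (row, col) with the origin at the top-left.
    """

    raster: np.ndarray
    grid_pitch_um: float = 100.0
    nominal_scale_um_per_px: float | None = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2 or min(self.raster.shape) < 64:
            raise InvalidParameterError("raster must be 2-D and at least 64x64")
        if self.grid_pitch_um <= 0:
            raise InvalidParameterError("grid pitch must be positive")


@dataclass
class ScaleMap:
    """Per-cell local scale measurements.

    axis is 'h' for horizontal spacings (between vertical lines, i.e. along
    columns) and 'v' for vertical spacings; center_px is the midpoint of the
    line pair along the measured axis.
    """

    axis: np.ndarray
    center_px: np.ndarray
    scale_um_per_px: np.ndarray

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis)
        self.center_px = np.asarray(self.center_px, dtype=float)
        self.scale_um_per_px = np.asarray(self.scale_um_per_px, dtype=float)
        if np.any(self.scale_um_per_px <= 0):
            raise InvalidParameterError("all scales must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": self.axis,
                "center_px": self.center_px,
                "scale_um_per_px": self.scale_um_per_px,
            }
        )


@dataclass
class ScaleSummary:
    """Summary statistics of a scale map."""

    mean_scale: float
    sd_scale: float
    delta_center_edge: float
    rel_nonuniformity_pct: float
    fov_diagonal_mm: float

    def __post_init__(self) -> None:
        if self.sd_scale < 0 or self.rel_nonuniformity_pct < 0:
            raise InvalidParameterError("spread statistics must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BathImage:
    """A single-plane image of a uniform fluorescent bath."""

    raster: np.ndarray
    scale_um_per_px: float

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise InvalidParameterError("raster must be 2-D")
        if self.scale_um_per_px <= 0:
            raise InvalidParameterError("scale must be strictly positive")


@dataclass
class UniformityReport:
    """Profiles and ROI statistics of a uniform-bath image."""

    row_profile: np.ndarray
    row_profile_sd: np.ndarray
    col_profile: np.ndarray
    col_profile_sd: np.ndarray
    roi_bounds_um: tuple
    mean: float
    sd: float
    sd_over_mean_pct: float

    def __post_init__(self) -> None:
        if self.sd_over_mean_pct < 0:
            raise InvalidParameterError("sd/mean must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("row_profile", "row_profile_sd", "col_profile", "col_profile_sd"):
            d[key] = np.asarray(d[key]).tolist()
        d["roi_bounds_um"] = list(self.roi_bounds_um)
        return d


def _refine_parabolic(profile: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """3-point parabolic sub-pixel refinement of extremum positions."""
    out = idx.astype(float)
    for j, i in enumerate(idx):
        if 0 < i < profile.size - 1:
            a, b, c = profile[i - 1], profile[i], profile[i + 1]
            denom = a - 2 * b + c
            if denom != 0:
                out[j] = i + 0.5 * (a - c) / denom
    return out


def _detect_lines_1d(profile: np.ndarray) -> np.ndarray:
    """Sub-pixel line positions from one axis projection.

    Polarity is auto-detected from the skewness of the projection: dark
    lines on a bright background produce a left-skewed profile, so troughs
    are detected on the inverted signal.  The projection is pre-smoothed
    with a 1 px Gaussian so the flat-bottomed trough of an anti-aliased
    line becomes locally quadratic and the 3-point parabola is unbiased.
    """
    span = profile.max() - profile.min()
    if span <= 0 or span < 1e-6 * max(abs(profile).max(), 1.0):
        return np.empty(0)
    dark_lines = skew(profile) < 0
    smooth = gaussian_filter1d(profile, sigma=1.0)
    signal = -smooth if dark_lines else smooth
    prominence = 0.25 * (signal.max() - signal.min())
    peaks, _ = find_peaks(signal, prominence=prominence, distance=4)
    return np.sort(_refine_parabolic(signal, peaks))


def detect_grid_lattice(image: CalibrationGridImage) -> dict[str, np.ndarray]:
    """Per-axis sorted sub-pixel grid-line coordinates.

    Returns ``{"x": columns of vertical lines, "y": rows of horizontal
    lines}``.  Raises :class:`DetectionFailureError` if fewer than 3 lines
    are found on either axis.
    """
    raster = image.raster
    x_lines = _detect_lines_1d(raster.mean(axis=0))
    y_lines = _detect_lines_1d(raster.mean(axis=1))
    if x_lines.size < 3 or y_lines.size < 3:
        raise DetectionFailureError(
            f"too few grid lines detected (x: {x_lines.size}, y: {y_lines.size}; "
            "need >= 3 per axis)"
        )
    return {"x": x_lines, "y": y_lines}


def local_scale_map(lattice: dict[str, np.ndarray], pitch_um: float) -> ScaleMap:
    """Per-cell scale S = pitch / spacing for each adjacent line pair."""
    if pitch_um <= 0:
        raise InvalidParameterError("pitch must be positive")
    axes, centers, scales = [], [], []
    for key, label in (("x", "h"), ("y", "v")):
        pos = np.asarray(lattice[key], dtype=float)
        if pos.size < 2:
            raise DetectionFailureError(f"need >= 2 lines on axis {key}")
        spacing = np.diff(pos)
        axes.extend([label] * spacing.size)
        centers.extend(((pos[:-1] + pos[1:]) / 2).tolist())
        scales.extend((pitch_um / spacing).tolist())
    return ScaleMap(
        axis=np.array(axes), center_px=np.array(centers), scale_um_per_px=np.array(scales)
    )


def scale_summary(
    smap: ScaleMap,
    image_shape: tuple[int, int],
    center_fraction: float = 0.33,
) -> ScaleSummary:
    """Mean/SD scale, centre-vs-edge deviation, and FOV diagonal.

    A cell is "centre" when its midpoint lies within the central
    ``center_fraction`` of its axis; the rest are "edge".  The deviation
    DeltaS = |mean(centre) - mean(edge)| and its percentage of the mean
    scale quantify field distortion.
    """
    if smap.scale_um_per_px.size < 4:
        raise InvalidParameterError("need at least 4 cells for summary statistics")
    n_rows, n_cols = image_shape
    half_extent = {"h": n_cols / 2.0, "v": n_rows / 2.0}
    mid = {"h": (n_cols - 1) / 2.0, "v": (n_rows - 1) / 2.0}
    is_center = np.array(
        [
            abs(c - mid[a]) <= center_fraction * half_extent[a]
            for a, c in zip(smap.axis, smap.center_px)
        ]
    )
    if not is_center.any() or is_center.all():
        raise InvalidParameterError("need both centre and edge cells; adjust center_fraction")
    scales = smap.scale_um_per_px
    mean_scale = float(scales.mean())
    delta = float(abs(scales[is_center].mean() - scales[~is_center].mean()))
    return ScaleSummary(
        mean_scale=mean_scale,
        sd_scale=float(scales.std(ddof=1)),
        delta_center_edge=delta,
        rel_nonuniformity_pct=100.0 * delta / mean_scale,
        fov_diagonal_mm=mean_scale * float(np.hypot(n_rows, n_cols)) / 1000.0,
    )


def uniformity_profiles(image: BathImage) -> dict[str, np.ndarray]:
    """Mean-intensity profiles (with +-1 SD bands) along rows and columns.

    ``row`` is intensity versus row index (averaged over columns), ``col``
    versus column index.
    """
    raster = image.raster
    return {
        "row": raster.mean(axis=1),
        "row_sd": raster.std(axis=1),
        "col": raster.mean(axis=0),
        "col_sd": raster.std(axis=0),
    }


def uniformity_stats(image: BathImage, roi_um: float = 700.0) -> UniformityReport:
    """SD/mean over a centred square ROI of side ``roi_um``.

    The ROI side is rounded to the nearest pixel; an odd leftover pixel is
    resolved toward the top-left.
    """
    raster = image.raster
    side_px = int(round(roi_um / image.scale_um_per_px))
    if side_px < 1 or side_px > min(raster.shape):
        raise InvalidParameterError(
            f"ROI of {roi_um} um ({side_px} px) does not fit in image {raster.shape}"
        )
    r0 = (raster.shape[0] - side_px) // 2
    c0 = (raster.shape[1] - side_px) // 2
    roi = raster[r0 : r0 + side_px, c0 : c0 + side_px]
    mean = float(roi.mean())
    sd = float(roi.std())
    profiles = uniformity_profiles(image)
    s = image.scale_um_per_px
    return UniformityReport(
        row_profile=profiles["row"],
        row_profile_sd=profiles["row_sd"],
        col_profile=profiles["col"],
        col_profile_sd=profiles["col_sd"],
        roi_bounds_um=(r0 * s, (r0 + side_px) * s, c0 * s, (c0 + side_px) * s),
        mean=mean,
        sd=sd,
        sd_over_mean_pct=100.0 * sd / mean if mean != 0 else 0.0,
    )
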