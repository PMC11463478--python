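"""Bead-based point-spread-function measurement.

Sub-resolution fluorescent beads (0.2 um, far below the two-photon
diffraction limit) imaged in a 3-D stack sample the effective PSF.  The
pipeline: detect isolated beads with a robust (median + MAD) threshold on a
lightly smoothed volume, extract a window around each with sub-voxel
recentring, fit Gaussian + offset profiles through the peak, and report the
radial and axial FWHM as mean +- SD across beads together with the
peak-normalised average PSF.

No bead-size deconvolution is applied by default: a 0.2 um bead broadens a
~0.76 um PSF by <0.4%, and raw FWHMs are what a user compares against the
diffraction limits.  A quadrature correction sqrt(FWHM^2 - d^2) is
available behind ``correct_bead_size=True``.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .errors import InvalidParameterError, MeasurementFailureError, NoBeadsError

__all__ = [
    "FWHM_PER_SIGMA",
    "BeadVolume",
    "BeadSet",
    "PsfEstimate",
    "detect_beads",
    "extract_bead_rois",
    "average_psf",
    "profile_fwhm",
    "psf_report",
]

#: FWHM of a Gaussian in units of its standard deviation: 2 sqrt(2 ln 2).
FWHM_PER_SIGMA: float = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Default extraction window (xy, z) in micrometres.
DEFAULT_WINDOW_UM: tuple[float, float] = (6.0, 20.0)


@dataclass
class BeadVolume:
    """A 3-D bead stack ordered (z, row, col) with voxel-size metadata."""

    stack: np.ndarray
    voxel_xy_um: float
    voxel_z_um: float
    bead_diameter_um: float = 0.2

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3 or self.stack.shape[0] < 5:
            raise InvalidParameterError("stack must be 3-D with at least 5 planes")
        if self.voxel_xy_um <= 0 or self.voxel_z_um <= 0:
            raise InvalidParameterError("voxel sizes must be positive")


@dataclass
class BeadSet:
    """Detected bead centroids (z, y, x; sub-voxel) with quality flags."""

    centroids: np.ndarray
    edge_clipped: np.ndarray
    overlapping: np.ndarray
    saturated: np.ndarray

    @property
    def kept(self) -> np.ndarray:
        return ~(self.edge_clipped | self.overlapping | self.saturated)

    @property
    def kept_count(self) -> int:
        return int(self.kept.sum())

    @property
    def kept_centroids(self) -> np.ndarray:
        return self.centroids[self.kept]


@dataclass
class PsfEstimate:
    """Bead-averaged PSF and per-bead FWHM statistics.

    The reported means and SDs are across per-bead fits (the +- spread a
    bead measurement quotes), not from the averaged PSF.
    """

    average_psf: np.ndarray
    radial_fwhm_nm: np.ndarray
    axial_fwhm_um: np.ndarray
    dr_mean_nm: float
    dr_sd_nm: float | None
    dz_mean_um: float
    dz_sd_um: float | None
    n_beads: int

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise InvalidParameterError("need at least one bead")
        if self.dr_mean_nm <= 0 or self.dz_mean_um <= 0:
            raise InvalidParameterError("FWHMs must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("average_psf")
        d["radial_fwhm_nm"] = np.asarray(self.radial_fwhm_nm).tolist()
        d["axial_fwhm_um"] = np.asarray(self.axial_fwhm_um).tolist()
        return d


def _window_half_voxels(
    volume: BeadVolume, window_um: tuple[float, float]
) -> tuple[int, int]:
    """(z, xy) half-window sizes in voxels for a physical window."""
    half_xy = int(round(window_um[0] / 2.0 / volume.voxel_xy_um))
    half_z = int(round(window_um[1] / 2.0 / volume.voxel_z_um))
    return max(half_z, 2), max(half_xy, 2)


def _refine_centroid(
    smooth: np.ndarray, peak: np.ndarray, radius: int = 2
) -> np.ndarray:
    """Background-subtracted intensity centroid in a small window."""
    lo = np.maximum(peak - radius, 0)
    hi = np.minimum(peak + radius + 1, smooth.shape)
    sub = smooth[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(float)
    sub = np.clip(sub - sub.min(), 0, None)
    total = sub.sum()
    if total <= 0:
        return peak.astype(float)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    return np.array([(g * sub).sum() / total for g in grids])


def detect_beads(
    volume: BeadVolume,
    min_separation_um: float = 10.8,
    threshold_sigmas: float = 5.0,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    saturation_level: float | None = None,
) -> BeadSet:
    """Find isolated beads in a stack.

    Local maxima of the sigma=1-voxel Gaussian-smoothed volume above
    background median + ``threshold_sigmas`` * MAD are candidate beads;
    the MAD noise scale is taken from the raw stack so that smoothing
    (which suppresses shot noise but not bead peaks) cannot promote
    residual noise maxima above the threshold.
    Pairs closer than ``min_separation_um`` (default twice a typical axial
    FWHM of ~5.4 um) are flagged overlapping; beads whose extraction window
    would leave the volume are flagged edge-clipped; voxels at
    ``saturation_level`` (or the dtype maximum for integer stacks) flag
    saturation.  Only unflagged beads are kept.
    """
    stack = volume.stack.astype(float)
    smooth = gaussian_filter(stack, sigma=1.0)
    bg = float(np.median(smooth))
    mad = float(np.median(np.abs(stack - np.median(stack)))) * 1.4826
    threshold = bg + threshold_sigmas * max(mad, 1e-12)
    # a 2-voxel border exclusion suppresses boundary artefacts of the
    # reflect-mode smoothing; real beads must sit a window away from the
    # edge regardless
    peaks = peak_local_max(
        smooth, min_distance=2, threshold_abs=threshold, exclude_border=2
    )
    if peaks.shape[0] == 0:
        raise NoBeadsError("no candidate beads above threshold")

    centroids = np.array([_refine_centroid(smooth, p) for p in peaks])

    # pairwise separations in physical units
    scale = np.array([volume.voxel_z_um, volume.voxel_xy_um, volume.voxel_xy_um])
    pos_um = centroids * scale
    n = pos_um.shape[0]
    overlapping = np.zeros(n, dtype=bool)
    if n > 1:
        d2 = np.sum((pos_um[:, None, :] - pos_um[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        overlapping = (d2.min(axis=1) < min_separation_um**2)

    half_z, half_xy = _window_half_voxels(volume, window_um)
    halves = np.array([half_z, half_xy, half_xy], dtype=float)
    limits = np.array(volume.stack.shape, dtype=float) - 1.0
    edge_clipped = np.any(
        (centroids - halves < 0) | (centroids + halves > limits), axis=1
    )

    if saturation_level is None and np.issubdtype(volume.stack.dtype, np.integer):
        saturation_level = float(np.iinfo(volume.stack.dtype).max)
    saturated = np.zeros(n, dtype=bool)
    if saturation_level is not None:
        for i, p in enumerate(peaks):
            saturated[i] = stack[tuple(p)] >= saturation_level

    beads = BeadSet(
        centroids=centroids,
        edge_clipped=edge_clipped,
        overlapping=overlapping,
        saturated=saturated,
    )
    if beads.kept_count == 0:
        raise NoBeadsError(
            f"no usable beads: {n} candidates, {int(overlapping.sum())} overlapping, "
            f"{int(edge_clipped.sum())} edge-clipped, {int(saturated.sum())} saturated"
        )
    return beads


def extract_bead_rois(
    volume: BeadVolume,
    beads: BeadSet,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    recenter_iterations: int = 3,
    interp_order: int = 3,
) -> list[np.ndarray]:
    """Extract an interpolated window around each kept bead.

    Each ROI is resampled on a grid centred on the bead so its intensity
    centroid sits at the window centre; the centring is iterated a few
    times from the detected centroid.  Resampling uses a cubic spline by
    default: linear interpolation convolves the data with a triangle
    kernel whose variance (up to 1/4 voxel^2 at half-voxel offsets)
    measurably broadens a 3-4 voxel FWHM, while the spline keeps the bias
    below ~0.3%.  Beads whose window would leave the volume are skipped
    with a warning.
    """
    half_z, half_xy = _window_half_voxels(volume, window_um)
    offsets = np.stack(
        np.meshgrid(
            np.arange(-half_z, half_z + 1, dtype=float),
            np.arange(-half_xy, half_xy + 1, dtype=float),
            np.arange(-half_xy, half_xy + 1, dtype=float),
            indexing="ij",
        )
    )
    stack = volume.stack.astype(float)
    limits = np.array(stack.shape, dtype=float) - 1.0
    halves = np.array([half_z, half_xy, half_xy], dtype=float)
    pad = 3  # crop margin for spline support and sub-voxel shifts
    rois: list[np.ndarray] = []
    for center in beads.kept_centroids:
        c = center.copy()
        roi = None
        for _ in range(max(recenter_iterations, 1)):
            if np.any(c - halves < 0) or np.any(c + halves > limits):
                roi = None
                break
            # resample inside an integer-aligned crop: spline prefiltering
            # the full stack per bead would dominate the runtime
            lo = np.maximum(np.floor(c - halves).astype(int) - pad, 0)
            hi = np.minimum(
                np.floor(c + halves).astype(int) + pad + 2, np.array(stack.shape)
            )
            crop = stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            c_local = c - lo
            coords = offsets + c_local[:, None, None, None]
            roi = map_coordinates(
                crop, coords.reshape(3, -1), order=interp_order
            ).reshape(offsets.shape[1:])
            sub = np.clip(roi - roi.min(), 0, None)
            total = sub.sum()
            if total <= 0:
                break
            com = np.array(
                [(g * sub).sum() / total for g in offsets]
            )
            if np.all(np.abs(com) < 0.01):
                break
            c = c + com
        if roi is None:
            _warnings.warn(
                f"bead at {np.round(center, 2)} skipped: window leaves the volume",
                stacklevel=2,
            )
            continue
        rois.append(roi)
    if not rois:
        raise NoBeadsError("all beads skipped during extraction")
    return rois


def average_psf(rois: list[np.ndarray]) -> np.ndarray:
    """Peak-normalise each ROI and average voxel-wise; output peak is 1."""
    if not rois:
        raise NoBeadsError("no ROIs to average")
    acc = np.zeros_like(rois[0], dtype=float)
    for roi in rois:
        peak = roi.max()
        if peak <= 0:
            raise InvalidParameterError("ROI with non-positive peak")
        acc += roi / peak
    acc /= len(rois)
    return acc / acc.max()


def _gaussian_offset(x, amp, mu, sigma, offset):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + offset


def _fit_profile_sigma(profile: np.ndarray) -> float:
    """Fitted Gaussian sigma (in samples) of a 1-D profile with offset."""
    profile = np.asarray(profile, dtype=float)
    span = profile.max() - profile.min()
    if span <= 0 or span < 1e-9 * max(abs(profile).max(), 1.0):
        raise MeasurementFailureError("flat profile")
    i_pk = int(np.argmax(profile))
    if i_pk in (0, profile.size - 1):
        raise MeasurementFailureError("profile peak on the boundary")
    x = np.arange(profile.size, dtype=float)
    w = np.clip(profile - profile.min(), 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - i_pk) ** 2) / np.sum(w))) or 1.0
    try:
        popt, _ = curve_fit(
            _gaussian_offset,
            x,
            profile,
            p0=[span, float(i_pk), sigma0, profile.min()],
            maxfev=5000,
        )
    except RuntimeError as exc:
        raise MeasurementFailureError(f"Gaussian profile fit failed: {exc}") from exc
    sigma = abs(float(popt[2]))
    if sigma < 1.0:
        _warnings.warn(
            f"fitted sigma {sigma:.2f} voxels < 1: FWHM is under-sampled", stacklevel=2
        )
    return sigma


def profile_fwhm(
    sub_volume: np.ndarray,
    axis: str,
    voxel_xy_um: float,
    voxel_z_um: float,
) -> float:
    """FWHM of a bead image along ``axis`` ('radial' or 'axial').

    The radial profile is the mean of the x- and y-profiles through the
    peak (the PSF is assumed radially symmetric); the axial profile runs
    along z.  A Gaussian + constant offset is fitted and
    FWHM = 2 sqrt(2 ln 2) sigma is converted to nm (radial) or um (axial).
    """
    sub_volume = np.asarray(sub_volume, dtype=float)
    if sub_volume.ndim != 3:
        raise InvalidParameterError("sub-volume must be 3-D")
    zp, yp, xp = np.unravel_index(int(np.argmax(sub_volume)), sub_volume.shape)
    if axis == "radial":
        px = sub_volume[zp, yp, :]
        py = sub_volume[zp, :, xp]
        n = min(px.size, py.size)
        profile = (px[:n] + py[:n]) / 2.0 if px.size == py.size else None
        if profile is None:
            sigma = (_fit_profile_sigma(px) + _fit_profile_sigma(py)) / 2.0
        else:
            sigma = _fit_profile_sigma(profile)
        return sigma * FWHM_PER_SIGMA * voxel_xy_um * 1000.0
    if axis == "axial":
        sigma = _fit_profile_sigma(sub_volume[:, yp, xp])
        return sigma * FWHM_PER_SIGMA * voxel_z_um
    raise InvalidParameterError("axis must be 'radial' or 'axial'")


def psf_report(
    volume: BeadVolume,
    min_separation_um: float = 10.8,
    threshold_sigmas: float = 5.0,
    window_um: tuple[float, float] = DEFAULT_WINDOW_UM,
    correct_bead_size: bool = False,
) -> PsfEstimate:
    """Full bead pipeline: detect, extract, per-bead FWHMs, averaged PSF.

    Per-bead fit failures are skipped with a warning; the mean +- SD across
    the remaining beads is reported.  With ``correct_bead_size=True`` the
    finite bead diameter is removed in quadrature.
    """
    beads = detect_beads(
        volume,
        min_separation_um=min_separation_um,
        threshold_sigmas=threshold_sigmas,
        window_um=window_um,
    )
    rois = extract_bead_rois(volume, beads, window_um=window_um)
    radial, axial = [], []
    for roi in rois:
        try:
            dr = profile_fwhm(roi, "radial", volume.voxel_xy_um, volume.voxel_z_um)
            dz = profile_fwhm(roi, "axial", volume.voxel_xy_um, volume.voxel_z_um)
        except MeasurementFailureError as exc:
            _warnings.warn(f"bead skipped in FWHM fit: {exc}", stacklevel=2)
            continue
        radial.append(dr)
        axial.append(dz)
    if not radial:
        raise NoBeadsError("no bead yielded a usable FWHM fit")
    radial_arr = np.asarray(radial)
    axial_arr = np.asarray(axial)
    if correct_bead_size:
        d_nm = volume.bead_diameter_um * 1000.0
        radial_arr = np.sqrt(np.clip(radial_arr**2 - d_nm**2, 0, None))
        axial_arr = np.sqrt(
            np.clip(axial_arr**2 - volume.bead_diameter_um**2, 0, None)
        )
    n = radial_arr.size
    return PsfEstimate(
        average_psf=average_psf(rois),
        radial_fwhm_nm=radial_arr,
        axial_fwhm_um=axial_arr,
        dr_mean_nm=float(radial_arr.mean()),
        dr_sd_nm=float(radial_arr.std(ddof=1)) if n >= 2 else None,
        dz_mean_um=float(axial_arr.mean()),
        dz_sd_um=float(axial_arr.std(ddof=1)) if n >= 2 else None,
        n_beads=n,
    )
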