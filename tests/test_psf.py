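import warnings

import numpy as np
import pytest

from tpqc import psf, synthetic
from tpqc.errors import MeasurementFailureError, NoBeadsError
from tpqc.psf import FWHM_PER_SIGMA


def _gaussian_volume(shape, center, sigmas, amplitude=100.0, background=5.0):
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    g = np.exp(
        -((z - center[0]) ** 2) / (2 * sigmas[0] ** 2)
        - ((y - center[1]) ** 2) / (2 * sigmas[1] ** 2)
        - ((x - center[2]) ** 2) / (2 * sigmas[2] ** 2)
    )
    return background + amplitude * g


def test_detect_beads_counts_default_phantom(bead_phantom):
    volume, truth = bead_phantom
    beads = psf.detect_beads(volume)
    assert beads.kept_count == truth.params["n_beads"] == 38


def test_detected_positions_match_truth(bead_phantom):
    volume, truth = bead_phantom
    beads = psf.detect_beads(volume)
    true = np.array(truth.params["positions_zyx_voxels"])
    det = beads.kept_centroids
    # match each true bead to its nearest detection, in voxel units
    for t in true:
        d = np.sqrt(((det - t) ** 2).sum(axis=1)).min()
        assert d <= 2.0  # recovered within a couple of voxels (sub-um in xy)


def test_noise_only_volume_raises():
    rng = np.random.default_rng(0)
    stack = rng.poisson(10.0, size=(10, 64, 64)).astype(float)
    volume = psf.BeadVolume(stack, voxel_xy_um=0.2, voxel_z_um=1.0)
    with pytest.raises(NoBeadsError):
        psf.detect_beads(volume)


def test_close_pair_flagged_overlapping():
    stack = _gaussian_volume((40, 64, 64), (20, 32, 20), (2.3, 1.6, 1.6))
    stack += _gaussian_volume((40, 64, 64), (20, 32, 44), (2.3, 1.6, 1.6), background=0.0)
    volume = psf.BeadVolume(stack, voxel_xy_um=0.2, voxel_z_um=1.0)
    # the pair is 24 px * 0.2 um = 4.8 um apart, below half min_separation
    with pytest.raises(NoBeadsError):
        psf.detect_beads(volume, min_separation_um=10.8)
    beads = psf.detect_beads(volume, min_separation_um=2.0, window_um=(4.0, 20.0))
    assert beads.kept_count == 2


def test_extraction_at_voxel_center_equals_cropping():
    center = (20, 32, 32)
    stack = _gaussian_volume((41, 65, 65), center, (2.3, 1.6, 1.6))
    volume = psf.BeadVolume(stack, voxel_xy_um=0.2, voxel_z_um=1.0)
    beads = psf.detect_beads(volume)
    rois = psf.extract_bead_rois(volume, beads, recenter_iterations=1)
    direct = stack[10:31, 17:48, 17:48]
    np.testing.assert_allclose(rois[0], direct, rtol=1e-7, atol=1e-7)


def test_extraction_recentres_subvoxel_offset():
    center = (20.0, 32.4, 31.7)
    stack = _gaussian_volume((41, 65, 65), center, (2.3, 1.6, 1.6))
    volume = psf.BeadVolume(stack, voxel_xy_um=0.2, voxel_z_um=1.0)
    beads = psf.detect_beads(volume)
    roi = psf.extract_bead_rois(volume, beads)[0]
    # the interpolated peak must land at the window centre
    peak = np.array(np.unravel_index(np.argmax(roi), roi.shape))
    centre = (np.array(roi.shape) - 1) / 2
    assert np.all(np.abs(peak - centre) <= 1)
    sub = np.clip(roi - roi.min(), 0, None)
    grids = np.meshgrid(*[np.arange(s) - (s - 1) / 2 for s in roi.shape], indexing="ij")
    com = np.array([(g * sub).sum() / sub.sum() for g in grids])
    assert np.all(np.abs(com) < 0.05)


def test_average_psf_idempotent_and_normalised():
    roi = _gaussian_volume((21, 31, 31), (10, 15, 15), (2.3, 1.6, 1.6), background=0.0)
    avg = psf.average_psf([roi, roi.copy(), roi.copy()])
    np.testing.assert_allclose(avg, roi / roi.max(), rtol=1e-12)
    assert avg.max() == pytest.approx(1.0)


def test_profile_fwhm_closed_form():
    """sigma = 2 px at 0.1 um/px gives FWHM = 0.4710 um radially."""
    stack = _gaussian_volume((31, 41, 41), (15, 20, 20), (2.0, 2.0, 2.0), background=0.0)
    fwhm_nm = psf.profile_fwhm(stack, "radial", voxel_xy_um=0.1, voxel_z_um=0.1)
    assert fwhm_nm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 2.0 * 0.1 * 1000, rel=1e-6)
    fwhm_um = psf.profile_fwhm(stack, "axial", voxel_xy_um=0.1, voxel_z_um=0.1)
    assert fwhm_um == pytest.approx(0.47096, rel=1e-4)


def _half_max_crossing_width(profile):
    """Independent FWHM oracle: linear interpolation of half-max crossings."""
    i_pk = int(np.argmax(profile))
    base = profile.min()
    half = base + (profile[i_pk] - base) / 2.0
    left = right = None
    for i in range(i_pk, 0, -1):
        if profile[i - 1] <= half:
            left = np.interp(half, [profile[i - 1], profile[i]], [i - 1, i])
            break
    for i in range(i_pk, profile.size - 1):
        if profile[i + 1] <= half:
            right = np.interp(half, [profile[i + 1], profile[i]], [i + 1.0, i])
            break
    return right - left


@pytest.mark.parametrize("sigma", [1.8, 2.5, 4.0])
def test_fwhm_fit_agrees_with_half_max_oracle(sigma):
    stack = _gaussian_volume(
        (41, 41, 41), (20, 20, 20), (sigma, sigma, sigma), background=3.0
    )
    fit_nm = psf.profile_fwhm(stack, "radial", voxel_xy_um=0.1, voxel_z_um=0.1)
    zp, yp, xp = np.unravel_index(np.argmax(stack), stack.shape)
    oracle_px = _half_max_crossing_width(stack[zp, yp, :])
    assert fit_nm == pytest.approx(oracle_px * 0.1 * 1000, rel=0.01)


def test_flat_profile_raises():
    with pytest.raises(MeasurementFailureError):
        psf.profile_fwhm(np.ones((11, 11, 11)), "radial", 0.1, 0.1)


def test_single_noiseless_bead_recovery(single_noiseless_bead):
    volume, truth = single_noiseless_bead
    estimate = psf.psf_report(volume)
    assert estimate.n_beads == 1
    assert estimate.dr_mean_nm == pytest.approx(truth.params["fwhm_r_nm"], rel=0.01)
    assert estimate.dz_mean_um == pytest.approx(truth.params["fwhm_z_um"], rel=0.01)
    assert estimate.dr_sd_nm is None  # no spread with a single bead


def test_report_invariant_to_intensity_scaling(single_noiseless_bead):
    volume, _ = single_noiseless_bead
    scaled = psf.BeadVolume(
        volume.stack * 7.5, voxel_xy_um=volume.voxel_xy_um, voxel_z_um=volume.voxel_z_um
    )
    a = psf.psf_report(volume)
    b = psf.psf_report(scaled)
    assert b.dr_mean_nm == pytest.approx(a.dr_mean_nm, rel=1e-9)
    assert b.dz_mean_um == pytest.approx(a.dz_mean_um, rel=1e-9)


def test_radial_fwhm_invariant_under_rotation(bead_phantom):
    volume, _ = bead_phantom
    rotated = psf.BeadVolume(
        np.rot90(volume.stack, k=1, axes=(1, 2)).copy(),
        voxel_xy_um=volume.voxel_xy_um,
        voxel_z_um=volume.voxel_z_um,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = psf.psf_report(volume)
        b = psf.psf_report(rotated)
    assert b.dr_mean_nm == pytest.approx(a.dr_mean_nm, rel=0.01)


def test_bead_size_quadrature_correction(single_noiseless_bead):
    volume, _ = single_noiseless_bead
    raw = psf.psf_report(volume, correct_bead_size=False)
    corr = psf.psf_report(volume, correct_bead_size=True)
    expected = np.sqrt(raw.dr_mean_nm**2 - 200.0**2)
    assert corr.dr_mean_nm == pytest.approx(expected, rel=1e-9)
    assert corr.dr_mean_nm < raw.dr_mean_nm


def test_undersampled_profile_warns():
    stack = _gaussian_volume((21, 21, 21), (10, 10, 10), (2.0, 0.7, 0.7), background=0.0)
    with pytest.warns(UserWarning, match="under-sampled"):
        psf.profile_fwhm(stack, "radial", 0.1, 0.1)
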