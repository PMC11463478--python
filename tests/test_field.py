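import numpy as np
import pytest

from tpqc import field, synthetic
from tpqc.errors import DetectionFailureError, InvalidParameterError


@pytest.fixture(scope="module")
def ideal_grid():
    return synthetic.gen_grid_image(noise_sd=0.0, seed=0)


@pytest.fixture(scope="module")
def noisy_grid():
    return synthetic.gen_grid_image(noise_sd=0.02, seed=1)


@pytest.fixture(scope="module")
def barrel_grid():
    return synthetic.gen_grid_image(barrel_k=5e-7, noise_sd=0.02, seed=2)


def test_ideal_grid_spacings_match_pitch(ideal_grid):
    image, truth = ideal_grid
    lattice = field.detect_grid_lattice(image)
    pitch_px = truth.params["pitch_px"]  # 36.10 px
    for axis in ("x", "y"):
        spacings = np.diff(lattice[axis])
        assert np.all(np.abs(spacings - pitch_px) < 0.05)


def test_uniform_image_detection_fails():
    image = field.CalibrationGridImage(np.full((128, 128), 3.0))
    with pytest.raises(DetectionFailureError):
        field.detect_grid_lattice(image)


def test_transposed_image_swaps_axes(noisy_grid):
    image, _ = noisy_grid
    lat = field.detect_grid_lattice(image)
    lat_t = field.detect_grid_lattice(
        field.CalibrationGridImage(image.raster.T, image.grid_pitch_um)
    )
    np.testing.assert_allclose(lat["x"], lat_t["y"], atol=1e-9)
    np.testing.assert_allclose(lat["y"], lat_t["x"], atol=1e-9)


def test_detection_invariant_to_intensity_scaling(noisy_grid):
    image, _ = noisy_grid
    lat = field.detect_grid_lattice(image)
    scaled = field.CalibrationGridImage(17.0 * image.raster, image.grid_pitch_um)
    lat_s = field.detect_grid_lattice(scaled)
    np.testing.assert_allclose(lat["x"], lat_s["x"], atol=1e-9)


def test_local_scale_arithmetic():
    lattice = {"x": np.array([0.0, 36.10, 72.20]), "y": np.array([0.0, 40.0, 80.0])}
    smap = field.local_scale_map(lattice, 100.0)
    h = smap.scale_um_per_px[smap.axis == "h"]
    assert h == pytest.approx([100 / 36.10, 100 / 36.10])
    # doubling the pitch doubles every scale
    smap2 = field.local_scale_map(lattice, 200.0)
    np.testing.assert_allclose(smap2.scale_um_per_px, 2 * smap.scale_um_per_px)


def test_mean_scale_recovery_and_flat_spread(noisy_grid):
    image, truth = noisy_grid
    smap = field.local_scale_map(field.detect_grid_lattice(image), 100.0)
    summary = field.scale_summary(smap, image.raster.shape)
    assert summary.mean_scale == pytest.approx(truth.params["scale_um_per_px"], rel=0.005)
    # distortion-free grid: per-cell spread below the sub-pixel tolerance
    assert summary.sd_scale < 0.01
    assert summary.delta_center_edge < 0.01


def test_barrel_distortion_center_edge_deviation(barrel_grid):
    """Centre cells magnify less than edge cells; sign and size follow the warp."""
    image, truth = barrel_grid
    k = truth.params["barrel_k"]
    smap = field.local_scale_map(field.detect_grid_lattice(image), 100.0)
    summary = field.scale_summary(smap, image.raster.shape)

    # brute-force oracle: warp the known ideal line coordinates, measure the
    # per-cell scales along the central row, summarise identically
    lines = np.array(truth.params["lines_x_ideal_px"])
    warped = lines * (1 + k * lines**2)
    center_col = (image.raster.shape[1] - 1) / 2.0
    oracle_map = field.ScaleMap(
        axis=np.array(["h"] * (lines.size - 1)),
        center_px=(warped[:-1] + warped[1:]) / 2 + center_col,
        scale_um_per_px=truth.params["scale_um_per_px"]
        * truth.params["pitch_px"]
        / np.diff(warped),
    )
    oracle = field.scale_summary(oracle_map, image.raster.shape)
    assert oracle.delta_center_edge > 0
    assert summary.delta_center_edge > 0.5 * oracle.delta_center_edge
    assert summary.delta_center_edge < 1.2 * oracle.delta_center_edge
    # per-cell scales measured through the projections track the central-row
    # warp to ~1.5% (full-axis projection averages the line curvature)
    measured_h = np.sort(smap.scale_um_per_px[smap.axis == "h"])
    np.testing.assert_allclose(
        measured_h, np.sort(oracle_map.scale_um_per_px), rtol=0.015
    )


def test_scale_summary_needs_center_and_edge():
    smap = field.ScaleMap(
        axis=np.array(["h"] * 4),
        center_px=np.array([250.0, 255.0, 260.0, 265.0]),  # all central
        scale_um_per_px=np.full(4, 2.77),
    )
    with pytest.raises(InvalidParameterError):
        field.scale_summary(smap, (512, 512))


def test_uniformity_profiles_constant_and_separable():
    const = field.BathImage(np.full((64, 64), 5.0), scale_um_per_px=1.0)
    prof = field.uniformity_profiles(const)
    np.testing.assert_allclose(prof["row"], 5.0)
    np.testing.assert_allclose(prof["row_sd"], 0.0, atol=1e-12)

    # separable vignette f(y) g(x): profiles proportional to f and g
    y = np.linspace(-1, 1, 64)[:, None]
    x = np.linspace(-1, 1, 80)[None, :]
    f, g = np.exp(-(y**2)), np.exp(-0.5 * x**2)
    img = field.BathImage(f * g, scale_um_per_px=1.0)
    prof = field.uniformity_profiles(img)
    np.testing.assert_allclose(prof["row"], f.ravel() * g.mean(), rtol=1e-12)
    np.testing.assert_allclose(prof["col"], g.ravel() * f.mean(), rtol=1e-12)
    # transposition swaps the two profiles
    prof_t = field.uniformity_profiles(field.BathImage((f * g).T, 1.0))
    np.testing.assert_allclose(prof_t["col"], prof["row"])


def test_uniformity_stats_matches_brute_force():
    bath, _ = synthetic.gen_bath_image(noise_sd=0.01, seed=3)
    report = field.uniformity_stats(bath, roi_um=700.0)
    side = int(round(700.0 / bath.scale_um_per_px))
    r0 = (bath.raster.shape[0] - side) // 2
    c0 = (bath.raster.shape[1] - side) // 2
    roi = bath.raster[r0 : r0 + side, c0 : c0 + side]
    expected = 100.0 * roi.std() / roi.mean()
    assert report.sd_over_mean_pct == pytest.approx(expected, rel=1e-10)


def test_uniformity_stats_constant_image_and_full_roi():
    img = field.BathImage(np.full((100, 100), 2.0), scale_um_per_px=1.0)
    assert field.uniformity_stats(img, roi_um=50.0).sd_over_mean_pct == 0.0
    assert field.uniformity_stats(img, roi_um=100.0).sd_over_mean_pct == 0.0
    with pytest.raises(InvalidParameterError):
        field.uniformity_stats(img, roi_um=101.0)


def test_default_bath_deviates_about_13_percent():
    """The default vignette reproduces a ~13% SD/mean over the 700 um ROI."""
    bath, _ = synthetic.gen_bath_image(noise_sd=0.01, seed=5)
    report = field.uniformity_stats(bath, roi_um=700.0)
    assert report.sd_over_mean_pct == pytest.approx(13.0, abs=0.5)
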