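# Methods

`tpqc` implements the quantitative desk-top procedures used to characterise
a laser-scanning two-photon microscope: first-order design arithmetic,
Pockels-cell transmission calibration, pulse-width inference from a
dispersion sweep, calibration-grid field-scale mapping, illumination
uniformity, and bead-based PSF measurement.  Seeded synthetic generators
stand in for the instrument so the entire pipeline is testable without
hardware.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Paraxial design model (`tpqc.optics`)

The excitation path is an ideal relay telescope (scan lens `fS`, tube lens
`fT`) conjugating the scanners to the objective back aperture, followed by
an ideal objective of focal length `fO`:

- magnification `M = fT / fS`; a beam angle θ at the scanner becomes `θ/M`
  at the pupil, and the focus translates by `2 fO tan(θ/M)` across the
  field.  `f·tan θ` is used rather than `f·θ`; at the ~2.7° pupil angles
  of a typical design the two differ by <0.1%, and the tangent is exact
  for an ideal lens.
- underfilling the back aperture scales the excitation NA linearly with
  the filled pupil fraction, capped at the nominal NA.  The default beam
  diameter (17.5 mm on a 20 mm pupil, fill 0.875) takes a nominal NA 0.8
  objective to an effective excitation NA of 0.70.
- two-photon diffraction-limited FWHMs: radial `0.6 λ / NA`, axial
  `2 λ n / NA²`.  Their ratio `(10/3)·n/NA` is an exact identity used as
  a property test.
- collection: isotropic emission into a cone of half-angle `arcsin(NA/n)`
  gives a solid-angle fraction `(1 − cos θ)/2` of the full sphere.

Angles are degrees at every interface, design lengths mm, resolution
outputs μm.  The scanner half-angle is interpreted as the *optical* beam
half-angle: that interpretation makes the relay arithmetic reproduce the
expected ~1.2 mm field for a ±10° scanner with `M = 3.75` and
`fO = 12.5 mm`, whereas a mechanical-angle reading would halve it.  No ray
tracing or aberration modelling is attempted.

## Pockels calibration (`tpqc.pockels`)

The electro-optic cell plus polarizer transmits
`P(V) = P0 sin²(πV/V0 + ϕ/2)`.  The fit is nonlinear least squares
(`scipy.optimize.curve_fit`) with data-driven initialisation: `P0` from the
sweep maximum; `V0` from the dominant frequency of the detrended sweep
(resampled to a uniform grid, Hann-windowed FFT, parabolic refinement of
the peak bin — the sweep is a raised cosine of period `V0`); the phase from
8 equispaced starting values, keeping the lowest-RMSE solution (ties broken
by the smallest phase after normalisation to `[0, 2π)`).  Multi-start is
needed because sin² admits reflections of the phase that are local optima.
Standard errors come from the fit covariance; under 2% additive noise the
`V0` interval `±3 SE` covers the truth in ≈99% of seeded replicates.

The dynamic range over a voltage window is computed in closed form from
the fitted model (endpoints plus stationary points at `πV/V0 + ϕ/2 = kπ/2`),
with the minimum floored at `1e-4·P0` because the ideal model reaches an
exact null.

## Dispersion sweep and pulse width (`tpqc.dispersion`)

A transform-limited Gaussian pulse of FWHM `Δτ` accumulating net group
delay dispersion `g` broadens to `Δτ·sqrt(1 + α g²/Δτ⁴)` with
`α = 16 ln²2 ≈ 7.6872` (natural logarithm — required by the Gaussian FWHM
identity).  Since two-photon fluorescence scales inversely with pulse
duration at fixed average power, sweeping the laser's dispersion
pre-compensation `φ` against a fixed system dispersion `φ0` gives

    I(φ) = I0 [1 + α (φ + φ0)² / Δτ⁴]^(−1/2).

Sign convention: applied compensation values are negative; the peak sits at
`φ = −φ0` and the fitted `gdd0_fs2` is the positive system-dispersion
magnitude.  Initialisation: `I0` from the maximum, `−φ0` from its location,
`Δτ` from the half-maximum width via the bracket-equals-4 identity
`|φ+φ0| = sqrt(3/α)·Δτ²`; when the sweep never reaches half maximum the
initial `Δτ` falls back to the half-span of the sweep and a flag is set.
A sweep with no interior maximum is fitted but flagged
(`no_interior_maximum`).  Real pulses can show non-Gaussian shoulders; the
model is kept purely Gaussian and the skewness of the residuals is
reported as a diagnostic instead of being modelled.

## Field scale and uniformity (`tpqc.field`)

Grid analysis is axis-separable: each axis is reduced to its mean
projection, line positions are found by peak detection
(`scipy.signal.find_peaks`, prominence 25% of the projection range,
polarity auto-detected from the projection skewness) and refined by a
3-point parabola.  The projection is pre-smoothed with a 1 px Gaussian:
an anti-aliased line produces a flat-bottomed trough on which the raw
parabola is undefined or biased, while after smoothing the trough is
locally quadratic and line positions on ideal grids are recovered to
better than 0.01 px.  Per adjacent line pair the local scale is
`S = pitch / spacing`, positioned at the pair midpoint.

The centre/edge split for the scale deviation `ΔS` uses the central third
of each axis (a cell is "centre" when its midpoint lies within ±1/6 of the
axis length around the middle); `ΔS/S·100%` is the reported
non-uniformity.  Projection-based detection deliberately trades accuracy
under 2-D distortion for robustness and simplicity: for a radial warp the
line curvature is averaged along the projection, which shifts all lines by
a common factor and attenuates the centre-edge contrast.  On the default
synthetic barrel phantom the pipeline recovers ~75% of the central-row
`ΔS` (0.08 vs 0.107 μm/px ground truth, i.e. ~3% vs ~4% of `S`); per-cell
scales still track the warp-field oracle to ~1.5%.  A full 2-D template
fit would remove this bias and is out of scope.

Bath uniformity is definitional: mean, SD and SD/mean over a centred
square ROI (side rounded to the nearest pixel, odd remainders resolved
toward the top-left), plus mean-intensity row/column profiles with ±1 SD
bands over the whole image.  The statistic is checked against a
brute-force recomputation on the identical pixel set to 1e-10 relative.

## Bead PSF measurement (`tpqc.psf`)

Detection: local maxima of the σ = 1 voxel Gaussian-smoothed stack above
`median + 5·MAD`.  The MAD noise scale is measured on the *raw* stack:
smoothing suppresses shot noise by a large factor while leaving bead peaks
nearly intact, so thresholding smoothed maxima against the smoothed-volume
MAD promotes residual noise maxima above threshold; the raw-stack scale
keeps the detector conservative with no loss of real beads at the SNRs of
interest.  A 2-voxel border is excluded (boundary artefacts of
reflect-mode smoothing).  Beads closer than `min_separation_um` (default
10.8 μm, twice a typical axial FWHM) are flagged overlapping; beads whose
extraction window would leave the volume are flagged edge-clipped;
saturated peaks are flagged for integer stacks.  Only unflagged beads are
kept.

Extraction: a window (default 6 μm laterally, 20 μm axially) is resampled
around each bead so its intensity centroid sits at the window centre,
iterating the centring up to 3 times.  Resampling uses a cubic spline:
linear interpolation convolves the data with a triangle kernel of variance
`f(1−f)` voxel² at fractional offset `f`, which broadens a 3.8-voxel FWHM
by up to ~5%; the spline keeps the noiseless bias below ~0.3%.

FWHM: 1-D profiles through the peak (x and y averaged for the radial
value — the PSF is assumed radially symmetric — and z for the axial value)
are fitted with a Gaussian plus constant offset, initialised from the
profile extrema and second moment; `FWHM = 2 sqrt(2 ln 2) σ`.  A warning
is issued when the fitted σ falls below 1 voxel (under-sampled).  The
reported mean ± SD is across per-bead fits, not from the averaged PSF,
matching how a bead measurement quotes its spread; the peak-normalised
voxel-wise average PSF is returned alongside.  No bead-size deconvolution
is applied by default (a 0.2 μm bead broadens a 0.76 μm PSF by <0.4%); a
quadrature correction is available behind `correct_bead_size=True`.

## Synthetic data (`tpqc.synthetic`)

Every generator is a pure function of (parameters, seed) via a private
`numpy` Generator; identical calls are bit-identical, and each dataset is
paired with a ground-truth record sufficient for brute-force recomputation
of any reported statistic.  Defaults describe one realistic mid-size
instrument and are fixed once:

- grid: 100 μm pitch at 2.77 μm/px on a 540 px canvas (large enough that
  a barrel-warped lattice stays fully visible), 6 μm dark lines on a
  bright background, anti-aliased by sub-pixel coverage; optional radial
  warp `r′ = r(1 + k r²)` about the centre, rendered by Newton inversion
  of the cubic per pixel.  The default distortion coefficient
  `k = 5e-7 px⁻²` was chosen analytically so the warp field itself yields
  a centre-edge scale deviation of ~0.1 μm/px (~4% of S) on this canvas.
- bath: centred Gaussian vignette; σ = 440 μm was solved in closed form so
  the SD/mean over a central 700×700 μm ROI is 13.0%.
- beads: 38 spots with Gaussian PSF of FWHM 760 nm radial / 5.4 μm axial
  (the effective two-photon PSF is modelled directly as a separable
  Gaussian, consistent with fitting Gaussians at analysis time) at
  0.2×0.2×1.0 μm voxels in a 50×512×512 volume; uniform sub-voxel
  positions by rejection sampling with ≥12 μm separation and
  window-plus-one-voxel edge margins; constant background (10 counts) and
  Poisson noise with the peak amplitude solved so amplitude/shot-noise at
  the peak equals `peak_snr` (default 20).
- sweeps: Pockels `P0 = 1`, `V0 = 120 V`, `ϕ = 0.6` over 0–240 V in 50
  points with additive Gaussian noise; dispersion `I0 = 1`,
  `φ0 = 20200 fs²`, `Δτ = 150 fs` over applied −30200…−10200 fs² in 60
  points with multiplicative Gaussian noise.

Noise models are declared, configurable defaults: additive Gaussian for
detector-dominated sweeps and 2-D rasters, Poisson for the photon-limited
bead volumes.

What the phantoms do not emulate: optical aberrations and depth-dependent
PSF changes, field curvature, scan-trajectory and line-rate artefacts,
detector pulse statistics, non-Gaussian pulse shoulders, and non-radial
distortion.  Passing the recovery tests therefore demonstrates estimator
correctness and calibration under the declared noise models, not
instrument performance on real hardware.

## Reporting (`tpqc.report`, `tpqc.cli`)

`run_qc` executes the configured analyses independently (one failure does
not abort the rest), juxtaposes measured resolution and field size against
the paraxial predictions, and serialises to JSON with stable key order;
absent blocks are omitted rather than written as nulls, timestamps can be
pinned for byte-identical reports, and the schema carries a major version
checked on load.  Exit status: 0 all requested blocks succeeded, 3 partial
success, 4 everything failed, 2 unreadable config.

## Problem sizes

The shipped tests and the reproduction script run entirely on synthetic
data sized for a desk-top run: 200 replicates for the sweep-fit
calibration statistics, single 540² / 512² rasters for grid and bath, and
one 50×512×512 bead volume (about 3 s to generate and 3 s to analyse).
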