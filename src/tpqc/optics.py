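"""Paraxial design arithmetic for a laser-scanning two-photon microscope.

The excitation path is modelled as an ideal relay telescope (scan lens +
tube lens) conjugating the scanners to the objective back aperture, followed
by an ideal objective.  All formulas are closed-form paraxial/geometric
expressions: relay magnification, angular demagnification of the scan angle,
field of view, underfill scaling of the excitation NA, Gaussian-focus
diffraction limits of the two-photon PSF, and the solid-angle fraction of
isotropic emission accepted by the collection cone.

Angles are degrees at every interface (converted to radians internally);
design lengths are millimetres, resolution outputs micrometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import InvalidParameterError

__all__ = [
    "ObjectiveSpec",
    "ScanRelaySpec",
    "DesignSummary",
    "relay_magnification",
    "scan_angle_at_pupil",
    "field_of_view_diameter",
    "effective_excitation_na",
    "diffraction_limits",
    "collection_fraction",
    "design_summary",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective lens parameters.

    focal_length_mm
        Effective focal length of the objective (e.g. 12.5 mm for a 16x
        objective with a 200 mm tube-lens convention).
    numerical_aperture
        Nominal NA of the objective; must be below the immersion index.
    immersion_index
        Refractive index of the immersion medium (1.33 for water).
    back_aperture_diameter_mm
        Entrance-pupil (back-aperture) diameter.
    """

    focal_length_mm: float
    numerical_aperture: float
    immersion_index: float
    back_aperture_diameter_mm: float

    def __post_init__(self) -> None:
        for name in (
            "focal_length_mm",
            "numerical_aperture",
            "immersion_index",
            "back_aperture_diameter_mm",
        ):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.numerical_aperture < self.immersion_index:
            raise InvalidParameterError("NA must be smaller than the immersion index")


@dataclass(frozen=True)
class ScanRelaySpec:
    """Scan-lens/tube-lens relay and scanner parameters.

    scan_half_angle_deg is the *optical* (beam) half-angle at the scanner,
    which is what the relay demagnifies onto the objective pupil.
    """

    scan_lens_focal_mm: float
    tube_lens_focal_mm: float
    scan_half_angle_deg: float
    beam_diameter_at_pupil_mm: float

    def __post_init__(self) -> None:
        if self.scan_lens_focal_mm <= 0 or self.tube_lens_focal_mm <= 0:
            raise InvalidParameterError("focal lengths must be positive")
        if not 0 < self.scan_half_angle_deg < 45:
            raise InvalidParameterError("scan half-angle must lie in (0, 45) degrees")
        if self.beam_diameter_at_pupil_mm <= 0:
            raise InvalidParameterError("beam diameter must be positive")


@dataclass(frozen=True)
class DesignSummary:
    """Bundle of the derived first-order design quantities."""

    magnification: float
    pupil_half_angle_deg: float
    fov_diameter_mm: float
    effective_na: float
    radial_limit_um: float
    axial_limit_um: float
    collection_fraction: float
    wavelength_nm: float

    def __post_init__(self) -> None:
        if not 0 < self.collection_fraction <= 0.5:
            raise InvalidParameterError("collection fraction must lie in (0, 0.5]")
        if self.radial_limit_um <= 0 or self.axial_limit_um <= 0:
            raise InvalidParameterError("diffraction limits must be positive")
        if self.fov_diameter_mm < 0:
            raise InvalidParameterError("field of view must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def relay_magnification(f_scan: float, f_tube: float) -> float:
    """Magnification M = f_tube / f_scan of the scan/tube-lens telescope."""
    if f_scan <= 0 or f_tube <= 0:
        raise InvalidParameterError("focal lengths must be positive")
    return f_tube / f_scan


def scan_angle_at_pupil(theta_scan_deg: float, magnification: float) -> float:
    """Optical half-angle at the objective pupil after angular demagnification.

    A relay of magnification M demagnifies beam angles by 1/M, so a ±10 deg
    scanner with M = 3.75 pivots the beam by ±2.67 deg at the back aperture.
    """
    if magnification <= 0:
        raise InvalidParameterError("magnification must be positive")
    return theta_scan_deg / magnification


def field_of_view_diameter(theta_pupil_deg: float, f_objective_mm: float) -> float:
    """Field-of-view diameter 2 f_O tan(theta) swept by the pivoting beam."""
    if not 0 <= theta_pupil_deg < 90:
        raise InvalidParameterError("pupil half-angle must lie in [0, 90) degrees")
    if f_objective_mm <= 0:
        raise InvalidParameterError("objective focal length must be positive")
    return 2.0 * f_objective_mm * math.tan(math.radians(theta_pupil_deg))


def effective_excitation_na(
    nominal_na: float, beam_diameter_mm: float, pupil_diameter_mm: float
) -> float:
    """Excitation NA after underfilling the back aperture.

    The excitation cone scales linearly with the filled pupil fraction,
    capped at the nominal NA for an overfilled pupil.
    """
    if nominal_na <= 0 or beam_diameter_mm <= 0 or pupil_diameter_mm <= 0:
        raise InvalidParameterError("all arguments must be positive")
    return nominal_na * min(1.0, beam_diameter_mm / pupil_diameter_mm)


def diffraction_limits(wavelength_nm: float, na: float, n: float) -> tuple[float, float]:
    """Two-photon diffraction-limited FWHM (radial, axial), both in um.

    Radial: 0.6 lambda / NA.  Axial: 2 lambda n / NA^2.
    """
    if wavelength_nm <= 0:
        raise InvalidParameterError("wavelength must be positive")
    if not 0 < na < n:
        raise InvalidParameterError("require 0 < NA < n")
    lam_um = wavelength_nm / 1000.0
    dr = 0.6 * lam_um / na
    dz = 2.0 * lam_um * n / na**2
    return dr, dz


def collection_fraction(na: float, n: float) -> float:
    """Fraction of 4*pi sr emission accepted by a cone of aperture NA in medium n.

    The half-angle is arcsin(NA/n); the spherical-cap solid angle gives
    (1 - cos(theta)) / 2, reaching one hemisphere (0.5) at NA = n.
    """
    if na <= 0 or n <= 0:
        raise InvalidParameterError("NA and n must be positive")
    if na > n:
        raise InvalidParameterError("NA cannot exceed the immersion index")
    theta = math.asin(na / n)
    return (1.0 - math.cos(theta)) / 2.0


def design_summary(
    objective: ObjectiveSpec, relay: ScanRelaySpec, wavelength_nm: float
) -> DesignSummary:
    """Compose the elementary design calculations into one record.

    Each field equals the corresponding single-operation result exactly.
    """
    m = relay_magnification(relay.scan_lens_focal_mm, relay.tube_lens_focal_mm)
    theta_obj = scan_angle_at_pupil(relay.scan_half_angle_deg, m)
    fov = field_of_view_diameter(theta_obj, objective.focal_length_mm)
    na_eff = effective_excitation_na(
        objective.numerical_aperture,
        relay.beam_diameter_at_pupil_mm,
        objective.back_aperture_diameter_mm,
    )
    dr, dz = diffraction_limits(wavelength_nm, na_eff, objective.immersion_index)
    frac = collection_fraction(objective.numerical_aperture, objective.immersion_index)
    return DesignSummary(
        magnification=m,
        pupil_half_angle_deg=theta_obj,
        fov_diameter_mm=fov,
        effective_na=na_eff,
        radial_limit_um=dr,
        axial_limit_um=dz,
        collection_fraction=frac,
        wavelength_nm=wavelength_nm,
    )
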