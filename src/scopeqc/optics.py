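"""First-order optics and photon-collection calculators.

Closed-form design arithmetic for a point-scanning two-photon microscope:
the scan/tube-lens relay (angular demagnification, predicted field of view),
the effective excitation numerical aperture of an underfilled objective,
two-photon diffraction-limited resolution, and the solid-angle fluorescence
collection efficiency of the objective.

All angles are held in radians internally; degrees appear only at the
interfaces. Nothing here rounds — reporting layers round for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ObjectiveSpec",
    "RelaySpec",
    "ResolutionEstimate",
    "CollectionEstimate",
    "relay_magnification",
    "pupil_scan_half_angle",
    "predicted_fov_diameter",
    "effective_excitation_na",
    "diffraction_limits",
    "collection_fraction",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """Objective lens parameters.

    Parameters
    ----------
    focal_length_mm : float
        Effective focal length of the objective in mm.
    na : float
        Numerical aperture, ``n * sin(theta)`` of the acceptance cone.
    immersion_index : float
        Refractive index of the immersion medium (1.33 for water).
    back_aperture_diameter_mm : float, optional
        Entrance-pupil (back aperture) diameter in mm, if known.
    """

    focal_length_mm: float
    na: float
    immersion_index: float
    back_aperture_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.focal_length_mm <= 0:
            raise ValueError("focal_length_mm must be > 0")
        if not 0 < self.na < self.immersion_index:
            raise ValueError("require 0 < na < immersion_index")
        if self.immersion_index < 1:
            raise ValueError("immersion_index must be >= 1")


@dataclass(frozen=True)
class RelaySpec:
    """Scan-lens/tube-lens relay and scanner parameters.

    The relay images the scanner plane onto the objective back aperture,
    magnifying the beam by M = f_T/f_S and demagnifying scan angles by 1/M.

    Parameters
    ----------
    scan_focal_length_mm, tube_focal_length_mm : float
        Focal lengths f_S and f_T in mm.
    scanner_half_angle_deg : float
        Optical deflection half-angle of the scanners (the "±θ" range).
    beam_fill_fraction : float
        Ratio of beam diameter to back-aperture diameter at the objective,
        in (0, 1]; 1 means a fully filled pupil.
    """

    scan_focal_length_mm: float
    tube_focal_length_mm: float
    scanner_half_angle_deg: float = 10.0
    beam_fill_fraction: float = 0.875

    def __post_init__(self) -> None:
        if self.scan_focal_length_mm <= 0 or self.tube_focal_length_mm <= 0:
            raise ValueError("focal lengths must be > 0")
        if self.scanner_half_angle_deg <= 0:
            raise ValueError("scanner_half_angle_deg must be > 0")
        if not 0 < self.beam_fill_fraction <= 1:
            raise ValueError("beam_fill_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ResolutionEstimate:
    """Two-photon diffraction-limited resolution (FWHM)."""

    radial_fwhm_nm: float
    axial_fwhm_um: float

    def __post_init__(self) -> None:
        if self.radial_fwhm_nm <= 0 or self.axial_fwhm_um <= 0:
            raise ValueError("FWHMs must be > 0")


@dataclass(frozen=True)
class CollectionEstimate:
    """Solid-angle collection efficiency of an objective.

    ``sphere_fraction`` is the fraction of the full 4π sr of an isotropic
    emitter that falls inside the acceptance cone; 0.5 is a hemisphere.
    """

    half_angle_deg: float
    sphere_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.sphere_fraction <= 0.5:
            raise ValueError("sphere_fraction must be in [0, 0.5]")


def relay_magnification(relay: RelaySpec) -> float:
    """Beam magnification M = f_T / f_S of the scan/tube-lens telescope."""
    return relay.tube_focal_length_mm / relay.scan_focal_length_mm


def pupil_scan_half_angle(relay: RelaySpec) -> float:
    """Scan half-angle at the objective back aperture, in degrees.

    The relay demagnifies scanner angles by the beam magnification:
    ±θ at the scanners becomes ±θ/M at the pupil.
    """
    return relay.scanner_half_angle_deg / relay_magnification(relay)


def predicted_fov_diameter(relay: RelaySpec, objective: ObjectiveSpec) -> float:
    """Predicted field-of-view diameter in mm.

    FOV = 2 · f_O · tan(θ/M), with the pupil half-angle θ/M from the relay.
    The tangent form is used; at the few-degree angles of a relayed scanner
    it differs from the small-angle form by < 0.1 %.
    """
    half_angle_rad = math.radians(pupil_scan_half_angle(relay))
    return 2.0 * objective.focal_length_mm * math.tan(half_angle_rad)


def effective_excitation_na(objective: ObjectiveSpec, relay: RelaySpec) -> float:
    """Excitation NA of an underfilled objective.

    A beam filling a fraction f of the back aperture excites with
    NA_eff = f · NA (capped at the nominal NA). Underfilling trades lateral
    and, more strongly, axial resolution for reduced sensitivity to motion
    and scattering.
    """
    return min(objective.na * relay.beam_fill_fraction, objective.na)


def diffraction_limits(wavelength_nm: float, na: float, n: float) -> ResolutionEstimate:
    """Two-photon diffraction-limited FWHM resolution.

    radial  δr = 0.6·λ/NA          (returned in nm)
    axial   δz = 2·λ·n/NA²         (returned in μm)

    Parameters
    ----------
    wavelength_nm : float
        Excitation wavelength in nm.
    na : float
        Effective excitation numerical aperture; must be < n.
    n : float
        Immersion refractive index.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength_nm must be > 0")
    if not 0 < na < n:
        raise ValueError("require 0 < na < n")
    radial_nm = 0.6 * wavelength_nm / na
    axial_um = 2.0 * wavelength_nm * n / na**2 * 1e-3
    return ResolutionEstimate(radial_fwhm_nm=radial_nm, axial_fwhm_um=axial_um)


def collection_fraction(na: float, n: float) -> CollectionEstimate:
    """Fraction of an isotropic emitter's light inside the objective's cone.

    Uniform-emitter solid-angle model: the acceptance half-angle is
    θ = asin(NA/n) and the captured fraction of the sphere is
    Ω/4π = (1 − cos θ)/2, reaching 0.5 (a full hemisphere) at NA = n.
    """
    if not 0 < na <= n:
        raise ValueError("require 0 < na <= n")
    half_angle = math.asin(na / n)
    fraction = (1.0 - math.cos(half_angle)) / 2.0
    return CollectionEstimate(
        half_angle_deg=math.degrees(half_angle), sphere_fraction=fraction
    )
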