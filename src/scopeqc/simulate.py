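"""Virtual microscope: a forward model that renders calibration samples.

The three image-based calibration samples of a two-photon rig — a chrome
grid target in a thin fluorescent film, a uniform fluorescein bath, and a
sparse volume of sub-resolution beads — are rendered with known ground
truth, so every analyzer in this package can be scored against the truth
that generated its input. Instrument scans (Pockels voltage scans, GDD
scans) are simulated from the same forward models the fitters assume.

Image formation chain
---------------------
ideal sample brightness (0..1)
  → center-anchored barrel distortion  r' = r·(1 + k·r²)
  → Gaussian PSF blur (lateral, or separable 3-D for volumes)
  → expected photons = photon_scale · brightness
  → Poisson shot noise + Gaussian read noise + constant offset
  → clip to the detector ceiling, quantize to integer counts

All randomness flows from one `numpy` generator seeded per render call;
identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .models import (
    DispersionParams,
    PockelsParams,
    ScanSeries,
    dispersion_fluorescence,
    pockels_transmission,
)

__all__ = [
    "VirtualScopeConfig",
    "GroundTruth",
    "k_for_edge_displacement",
    "barrel_map",
    "invert_barrel_map",
    "render_grid",
    "render_bath",
    "render_bead_volume",
    "simulate_pockels_scan",
    "simulate_dispersion_scan",
    "BeadPlacementError",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class BeadPlacementError(RuntimeError):
    """Raised when beads cannot be placed at the requested separation."""


@dataclass(frozen=True)
class VirtualScopeConfig:
    """Forward-model specification of the virtual instrument.

    Defaults emulate the characterized instrument: 512×512 field at
    2.77 μm/px (≈1.4 mm square, 2.0 mm diagonal), a two-photon PSF of
    0.79 μm radial and 5.0 μm axial FWHM, a 15-bit detector ceiling of
    32768 counts, and mixed Poisson–Gaussian detection noise.
    """

    image_shape: tuple[int, ...] = (512, 512)
    pixel_size_um: float = 2.77
    z_step_um: float = 0.5
    psf_radial_fwhm_um: float = 0.79
    psf_axial_fwhm_um: float = 5.0
    distortion_k: float = 0.0  # barrel coefficient, units 1/μm²
    vignette_sigma: float = 0.8  # Gaussian width as fraction of half-diagonal
    photon_scale: float = 5000.0  # expected photons at unit brightness
    read_noise_sd: float = 3.0  # counts
    offset: float = 100.0  # counts
    bit_depth: int = 16
    saturation: int = 32768  # detector ceiling in counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel sizes must be > 0")
        if self.psf_radial_fwhm_um <= 0 or self.psf_axial_fwhm_um <= 0:
            raise ValueError("PSF FWHMs must be > 0")
        if self.bit_depth not in (12, 16):
            raise ValueError("bit_depth must be 12 or 16")
        if not 0 < self.saturation <= 2**self.bit_depth - 1:
            raise ValueError("saturation must be in (0, 2**bit_depth - 1]")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        # guard: distortion must stay single-valued over the field
        half_diag = self.half_diagonal_um(lateral_only=True)
        if self.distortion_k < 0 and 3 * abs(self.distortion_k) * half_diag**2 >= 1:
            raise ValueError("distortion_k too negative; map folds over the field")

    def lateral_shape(self) -> tuple[int, int]:
        return tuple(self.image_shape[-2:])  # type: ignore[return-value]

    def half_diagonal_um(self, lateral_only: bool = True) -> float:
        ny, nx = self.lateral_shape()
        return 0.5 * math.hypot(nx * self.pixel_size_um, ny * self.pixel_size_um)


@dataclass(frozen=True)
class GroundTruth:
    """The true quantities a rendered dataset was generated from."""

    pixel_size_um: float
    z_step_um: float | None = None
    distortion_k: float | None = None
    vignette_field: np.ndarray | None = field(default=None, repr=False)
    bead_centers_um: np.ndarray | None = None  # (n, 3) z, y, x in μm
    psf_radial_fwhm_um: float | None = None
    psf_axial_fwhm_um: float | None = None
    pockels: PockelsParams | None = None
    dispersion: DispersionParams | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        """JSON-serializable view (arrays as lists, params as dicts)."""
        out: dict[str, Any] = {
            "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.z_step_um,
            "distortion_k": self.distortion_k,
            "psf_radial_fwhm_um": self.psf_radial_fwhm_um,
            "psf_axial_fwhm_um": self.psf_axial_fwhm_um,
        }
        if self.bead_centers_um is not None:
            out["bead_centers_um"] = self.bead_centers_um.tolist()
        if self.pockels is not None:
            out["pockels"] = {
                "p0_mw": self.pockels.p0_mw,
                "v0_v": self.pockels.v0_v,
                "phase_rad": self.pockels.phase_rad,
            }
        if self.dispersion is not None:
            out["dispersion"] = {
                "i0": self.dispersion.i0,
                "phi0_fs2": self.dispersion.phi0_fs2,
                "delta_tau_fs": self.dispersion.delta_tau_fs,
            }
        out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# geometry


def k_for_edge_displacement(percent: float, half_diagonal_um: float) -> float:
    """Barrel coefficient giving a ``percent`` radial displacement at the
    field corner: k·R² = percent/100 at R = half-diagonal."""
    return (percent / 100.0) / half_diagonal_um**2


def barrel_map(y_um: np.ndarray, x_um: np.ndarray, k: float):
    """Forward barrel map about the field center: r → r·(1 + k·r²).

    Maps image-plane coordinates (μm from center) to the sample coordinates
    they observe; with k > 0 the periphery samples the object faster than
    the center, so a fixed-pitch target appears compressed toward the edges
    (magnification falls with radius — barrel distortion).
    """
    r2 = y_um**2 + x_um**2
    scale = 1.0 + k * r2
    return y_um * scale, x_um * scale


def invert_barrel_map(
    y_um: np.ndarray, x_um: np.ndarray, k: float, tol: float = 1e-9, max_iter: int = 60
):
    """Numerically invert :func:`barrel_map` (fixed-point iteration on radius)."""
    r_target = np.sqrt(np.asarray(y_um) ** 2 + np.asarray(x_um) ** 2)
    r = r_target.copy()
    for _ in range(max_iter):
        r_new = r_target / (1.0 + k * r**2)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(r_target > 0, r / r_target, 1.0)
    return y_um * ratio, x_um * ratio


def _pixel_grid_um(shape: tuple[int, int], pixel_size_um: float):
    """Physical (μm) coordinates of pixel centers, origin at the image center."""
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_size_um
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_size_um
    return np.meshgrid(y, x, indexing="ij")


# ---------------------------------------------------------------------------
# detection chain


def apply_detection_noise(
    brightness: np.ndarray, config: VirtualScopeConfig, rng: np.random.Generator
) -> np.ndarray:
    """Photon + read noise + offset, clipped and quantized to uint16 counts."""
    photons = rng.poisson(np.clip(brightness, 0.0, None) * config.photon_scale)
    counts = photons + rng.normal(0.0, config.read_noise_sd, brightness.shape)
    counts = counts + config.offset
    counts = np.clip(np.rint(counts), 0, config.saturation)
    return counts.astype(np.uint16)


def _noiseless_counts(brightness: np.ndarray, config: VirtualScopeConfig) -> np.ndarray:
    counts = brightness * config.photon_scale + config.offset
    return np.clip(counts, 0, config.saturation)


# ---------------------------------------------------------------------------
# renderers


def render_grid(
    config: VirtualScopeConfig,
    pitch_um: float = 100.0,
    bar_width_um: float = 10.0,
    noise: bool = True,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a fixed-pitch grid target in a bright fluorescent film.

    Dark chrome bars (brightness 0.05) on a fluorescent background
    (brightness 1.0), mapped through the barrel distortion, blurred by the
    lateral PSF, then passed through the detection chain. Bars are centered
    on integer multiples of the pitch in sample space.
    """
    if not pitch_um > bar_width_um > config.pixel_size_um:
        raise ValueError("require pitch > bar_width > pixel size")
    if pitch_um < 3 * config.pixel_size_um:
        raise ValueError("grid pitch below 3 px cannot be rendered or resolved")
    shape = config.lateral_shape()
    yy, xx = _pixel_grid_um(shape, config.pixel_size_um)
    y_s, x_s = barrel_map(yy, xx, config.distortion_k)

    def bar(coord):  # distance to the nearest bar center line
        d = np.abs((coord + pitch_um / 2.0) % pitch_um - pitch_um / 2.0)
        return d < bar_width_um / 2.0

    brightness = np.where(bar(y_s) | bar(x_s), 0.05, 1.0)
    sigma_px = config.psf_radial_fwhm_um / _FWHM_PER_SIGMA / config.pixel_size_um
    brightness = gaussian_filter(brightness, sigma_px, mode="nearest")
    rng = np.random.default_rng(config.seed)
    image = (
        apply_detection_noise(brightness, config, rng)
        if noise
        else _noiseless_counts(brightness, config)
    )
    truth = GroundTruth(
        pixel_size_um=config.pixel_size_um,
        distortion_k=config.distortion_k,
        psf_radial_fwhm_um=config.psf_radial_fwhm_um,
        extras={"pitch_um": pitch_um, "bar_width_um": bar_width_um},
    )
    return image, truth


def render_bath(
    config: VirtualScopeConfig, noise: bool = True
) -> tuple[np.ndarray, GroundTruth]:
    """Render a uniform fluorescein bath with radial Gaussian vignetting.

    True brightness is constant; detected brightness falls off as
    exp(−r²/2σ²) with σ = ``vignette_sigma`` × half-diagonal. The noiseless
    vignette field is stored in the ground truth.
    """
    shape = config.lateral_shape()
    yy, xx = _pixel_grid_um(shape, config.pixel_size_um)
    sigma_um = config.vignette_sigma * config.half_diagonal_um()
    vignette = np.exp(-(yy**2 + xx**2) / (2.0 * sigma_um**2))
    rng = np.random.default_rng(config.seed)
    image = (
        apply_detection_noise(vignette, config, rng)
        if noise
        else _noiseless_counts(vignette, config)
    )
    truth = GroundTruth(
        pixel_size_um=config.pixel_size_um,
        vignette_field=vignette,
        extras={"vignette_sigma_um": sigma_um},
    )
    return image, truth


def _integrated_gaussian_1d(centers_px: float, sigma_px: float, n: int, cut: float):
    """Per-pixel integral of a unit-area Gaussian along one axis (±cut·σ)."""
    lo = max(0, int(math.floor(centers_px - cut * sigma_px)))
    hi = min(n - 1, int(math.ceil(centers_px + cut * sigma_px)))
    if hi < lo:
        return lo, np.zeros(0)
    idx = np.arange(lo, hi + 1)
    a = (idx - 0.5 - centers_px) / (math.sqrt(2.0) * sigma_px)
    b = (idx + 0.5 - centers_px) / (math.sqrt(2.0) * sigma_px)
    return lo, 0.5 * (erf(b) - erf(a))


def render_bead_volume(
    config: VirtualScopeConfig,
    n_beads: int = 38,
    min_separation_um: float = 6.0,
    bead_flux: float = 1.0,
    noise: bool = True,
    max_tries_per_bead: int = 1000,
    edge_margin_um: tuple[float, float] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a sparse volume of sub-resolution beads.

    Beads are point emitters at uniformly random continuous positions, at
    least ``min_separation_um`` apart (3-D distance) and at least
    ``edge_margin_um`` = (axial, lateral) from the volume faces (default:
    one PSF FWHM per axis), rendered as separable 3-D Gaussians integrated
    per voxel (lateral FWHM ``psf_radial_fwhm_um``, axial FWHM
    ``psf_axial_fwhm_um``), with total flux ``bead_flux`` per bead (in units
    of brightness·voxel) truncated at ±4σ.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if len(config.image_shape) != 3:
        raise ValueError("config.image_shape must be 3-D (nz, ny, nx)")
    nz, ny, nx = config.image_shape
    if edge_margin_um is None:
        edge_margin_um = (config.psf_axial_fwhm_um, config.psf_radial_fwhm_um)
    margin_z, margin_xy = edge_margin_um
    extent = np.array(
        [nz * config.z_step_um, ny * config.pixel_size_um, nx * config.pixel_size_um]
    )
    lo = np.array([margin_z, margin_xy, margin_xy])
    hi = extent - lo
    if np.any(hi <= lo):
        raise BeadPlacementError("volume too small for edge margins")

    rng = np.random.default_rng(config.seed)
    centers: list[np.ndarray] = []
    for _ in range(n_beads):
        for _try in range(max_tries_per_bead):
            cand = lo + rng.random(3) * (hi - lo)
            if all(np.linalg.norm(cand - c) >= min_separation_um for c in centers):
                centers.append(cand)
                break
        else:
            raise BeadPlacementError(
                f"could not place bead {len(centers) + 1}/{n_beads} at "
                f"{min_separation_um} um separation after {max_tries_per_bead} tries"
            )
    centers_arr = np.asarray(centers)

    sig_z = config.psf_axial_fwhm_um / _FWHM_PER_SIGMA / config.z_step_um
    sig_xy = config.psf_radial_fwhm_um / _FWHM_PER_SIGMA / config.pixel_size_um
    brightness = np.zeros((nz, ny, nx), dtype=float)
    spacing = np.array([config.z_step_um, config.pixel_size_um, config.pixel_size_um])
    for c in centers_arr:
        cz, cy, cx = c / spacing - 0.5  # voxel-center coordinates
        z0, wz = _integrated_gaussian_1d(cz, sig_z, nz, cut=4.0)
        y0, wy = _integrated_gaussian_1d(cy, sig_xy, ny, cut=4.0)
        x0, wx = _integrated_gaussian_1d(cx, sig_xy, nx, cut=4.0)
        if min(wz.size, wy.size, wx.size) == 0:
            continue
        brightness[
            z0 : z0 + wz.size, y0 : y0 + wy.size, x0 : x0 + wx.size
        ] += bead_flux * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]

    volume = (
        apply_detection_noise(brightness, config, rng)
        if noise
        else _noiseless_counts(brightness, config)
    )
    truth = GroundTruth(
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        bead_centers_um=centers_arr,
        psf_radial_fwhm_um=config.psf_radial_fwhm_um,
        psf_axial_fwhm_um=config.psf_axial_fwhm_um,
        extras={"bead_flux": bead_flux, "brightness_peak": float(brightness.max())},
    )
    return volume, truth


# ---------------------------------------------------------------------------
# instrument scans


def simulate_pockels_scan(
    params: PockelsParams,
    v_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScanSeries:
    """Simulate a Pockels voltage scan: sin² transmission + Gaussian noise (mW)."""
    v_grid = np.asarray(v_grid, dtype=float)
    power = pockels_transmission(v_grid, params)
    if noise_sd > 0:
        power = power + np.random.default_rng(seed).normal(0, noise_sd, v_grid.shape)
    return ScanSeries(v_grid, power, units=("V", "mW"))


def simulate_dispersion_scan(
    params: DispersionParams,
    phi_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ScanSeries:
    """Simulate a GDD scan: pulse-broadening response + Gaussian noise (a.u.)."""
    phi_grid = np.asarray(phi_grid, dtype=float)
    intensity = dispersion_fluorescence(phi_grid, params)
    if noise_sd > 0:
        intensity = intensity + np.random.default_rng(seed).normal(
            0, noise_sd, phi_grid.shape
        )
    return ScanSeries(phi_grid, intensity, units=("fs2", "au"))
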