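"""Shared fixtures: instrument specs and rendered synthetic datasets.

Expensive renders are session-scoped so detection/recovery tests and the
end-to-end acceptance checks share one volume.
"""

from __future__ import annotations

import pytest

from scopeqc import ObjectiveSpec, RelaySpec
from scopeqc import simulate as sim
from scopeqc.psf import ImageVolume

# bead-volume study conditions: 38 beads, PSF FWHMs 0.79/5.0 um, sampled at
# 0.2 um laterally and 0.5 um axially
BEAD_TRUTH = {"radial_fwhm_um": 0.79, "axial_fwhm_um": 5.0, "n_beads": 38}
BEAD_CONFIG = dict(
    image_shape=(120, 384, 384),
    pixel_size_um=0.2,
    z_step_um=0.5,
    psf_radial_fwhm_um=0.79,
    psf_axial_fwhm_um=5.0,
    seed=3,
)
# keep generated beads clear of the analyzer's fitting-window edge margins
BEAD_MARGIN_UM = (20.0, 4.0)


@pytest.fixture(scope="session")
def relay_spec() -> RelaySpec:
    """The characterized design: f_S 100 mm, f_T 375 mm, ±10 deg scanners."""
    return RelaySpec(
        scan_focal_length_mm=100.0,
        tube_focal_length_mm=375.0,
        scanner_half_angle_deg=10.0,
        beam_fill_fraction=0.875,
    )


@pytest.fixture(scope="session")
def objective_spec() -> ObjectiveSpec:
    """16x long-working-distance water objective: f 12.5 mm, NA 0.8."""
    return ObjectiveSpec(focal_length_mm=12.5, na=0.8, immersion_index=1.33)


@pytest.fixture(scope="session")
def bead_volume_38() -> tuple[ImageVolume, sim.GroundTruth]:
    """A 38-bead synthetic z-stack at the design PSF, with photon noise."""
    cfg = sim.VirtualScopeConfig(**BEAD_CONFIG)
    volume, truth = sim.render_bead_volume(
        cfg,
        n_beads=BEAD_TRUTH["n_beads"],
        min_separation_um=6.0,
        bead_flux=20.0,
        edge_margin_um=BEAD_MARGIN_UM,
    )
    return ImageVolume(volume, cfg.pixel_size_um, cfg.z_step_um), truth


@pytest.fixture(scope="session")
def grid_image_clean() -> tuple:
    """Distortion-free 100 um grid at 2.77 um/px with detection noise."""
    cfg = sim.VirtualScopeConfig(seed=1)
    image, truth = sim.render_grid(cfg, pitch_um=100.0)
    return image, cfg, truth


@pytest.fixture(scope="session")
def grid_image_4pct() -> tuple:
    """Same grid with a 4 % corner barrel displacement."""
    base = sim.VirtualScopeConfig()
    k = sim.k_for_edge_displacement(4.0, base.half_diagonal_um())
    cfg = sim.VirtualScopeConfig(seed=1, distortion_k=k)
    image, truth = sim.render_grid(cfg, pitch_um=100.0)
    return image, cfg, truth
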