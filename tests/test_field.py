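"""Grid scale maps, distortion metric, bath uniformity, FOV summary."""

import math

import numpy as np
import pandas as pd
import pytest

from scopeqc import ObjectiveSpec, RelaySpec, predicted_fov_diameter
from scopeqc import simulate as sim
from scopeqc.field import (
    FovSummary,
    GridDetectionError,
    ScaleMap,
    distortion_metric,
    fov_summary,
    grid_scale_map,
    uniformity_stats,
)


def synthetic_scale_map(scales_by_cell, image_shape=(512, 512), pitch_um=100.0):
    """Build a ScaleMap directly from (x_px, y_px, scale, axis) rows."""
    df = pd.DataFrame(
        scales_by_cell, columns=["x_px", "y_px", "scale_um_per_px", "axis"]
    )
    s = df["scale_um_per_px"].to_numpy()
    return ScaleMap(
        cells=df,
        image_shape=image_shape,
        pitch_um=pitch_um,
        scale_mean=float(s.mean()),
        scale_sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
    )


def lattice_cells(scale_fn, n=5, image_shape=(512, 512)):
    """Cells on an n x n lattice with scale given by scale_fn(u, v) in [-1, 1]."""
    ny, nx = image_shape
    rows = []
    for iy in range(n):
        for ix in range(n):
            x = (ix + 0.5) / n * nx
            y = (iy + 0.5) / n * ny
            u = (x - nx / 2) / (nx / 2)
            v = (y - ny / 2) / (ny / 2)
            for axis in ("x", "y"):
                rows.append((x, y, scale_fn(u, v), axis))
    return rows


class TestGridScaleMap:
    @pytest.mark.parametrize("px", [1.0, 2.77, 5.0])
    def test_scale_recovered_within_half_percent(self, px):
        cfg = sim.VirtualScopeConfig(pixel_size_um=px, seed=1)
        image, _ = sim.render_grid(cfg, pitch_um=100.0)
        m = grid_scale_map(image, pitch_um=100.0)
        assert m.scale_mean == pytest.approx(px, rel=0.005)
        assert not m.flags

    def test_uses_session_grid(self, grid_image_clean):
        image, cfg, _ = grid_image_clean
        m = grid_scale_map(image, pitch_um=100.0)
        assert m.scale_mean == pytest.approx(2.77, rel=0.005)
        assert {"x", "y"} == set(m.cells["axis"].unique())

    def test_rotation_estimated_and_removed(self, grid_image_clean):
        from scipy import ndimage

        image, _, _ = grid_image_clean
        rotated = ndimage.rotate(
            image.astype(float), -1.5, reshape=False, order=1, mode="nearest"
        )
        m = grid_scale_map(rotated, pitch_um=100.0)
        # grid_angle_deg is the correction applied, opposite in sign to the
        # rotation introduced above
        assert m.grid_angle_deg == pytest.approx(1.5, abs=0.3)
        assert m.scale_mean == pytest.approx(2.77, rel=0.01)

    def test_featureless_image_rejected(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(1000.0, 3.0, size=(256, 256))
        with pytest.raises(GridDetectionError):
            grid_scale_map(flat, pitch_um=100.0)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            grid_scale_map(np.zeros((4, 4, 4)), pitch_um=100.0)


class TestDistortionMetric:
    def test_uniform_map_scores_zero(self):
        m = synthetic_scale_map(lattice_cells(lambda u, v: 2.77))
        assert distortion_metric(m) == pytest.approx(0.0, abs=1e-12)

    def test_worked_center_edge_ratio(self):
        # center cells at 2.70 um/px, edge cells at 2.80: the deviation is
        # 0.10 / mean. With a 5x5 lattice, center block = the single middle
        # cell, edge ring = the outer 16 cells, mean over all 25 = 2.7936
        def scale(u, v):
            return 2.70 if max(abs(u), abs(v)) <= 0.3 else 2.80

        m = synthetic_scale_map(lattice_cells(scale))
        expected = 100.0 * 0.10 / m.scale_mean
        assert distortion_metric(m) == pytest.approx(expected, rel=1e-9)
        assert round(distortion_metric(m)) == 4

    def test_monotone_in_applied_distortion(self):
        # barrel strength up => larger center-vs-edge metric
        metrics = []
        base = sim.VirtualScopeConfig()
        for pct in (0.0, 1.0, 2.0, 3.0, 4.0):
            k = sim.k_for_edge_displacement(pct, base.half_diagonal_um())
            cfg = sim.VirtualScopeConfig(seed=1, distortion_k=k)
            image, _ = sim.render_grid(cfg, pitch_um=100.0)
            metrics.append(distortion_metric(grid_scale_map(image, 100.0)))
        assert all(b > a for a, b in zip(metrics, metrics[1:]))

    def test_four_percent_displacement_measured(self, grid_image_4pct):
        image, _, _ = grid_image_4pct
        m = grid_scale_map(image, pitch_um=100.0)
        metric = distortion_metric(m)
        # center-vs-edge scale contrast of a 4% corner-displacement barrel;
        # the ring averages radii below the corner, so slightly under 4
        assert 2.0 <= metric <= 6.0

    def test_too_few_cells_rejected(self):
        rows = [(100.0, 100.0, 2.77, "x"), (200.0, 100.0, 2.77, "y")]
        m = synthetic_scale_map(rows)
        with pytest.raises(ValueError):
            distortion_metric(m)


class TestUniformityStats:
    def test_constant_image_scores_zero(self):
        img = np.full((101, 101), 1234.0)
        res = uniformity_stats(img, roi_um=100.0, pixel_size_um=2.77)
        assert res.percent_deviation == 0.0
        assert res.mean_counts == 1234.0

    def test_single_pixel_roi_degenerate(self):
        img = np.full((11, 11), 10.0)
        res = uniformity_stats(img, roi_um=1.0, pixel_size_um=2.77)
        assert res.percent_deviation == 0.0
        assert "degenerate_roi" in res.flags

    def test_roi_larger_than_image_rejected(self):
        img = np.zeros((32, 32))
        with pytest.raises(ValueError):
            uniformity_stats(img, roi_um=500.0, pixel_size_um=2.77)

    def test_vignetted_bath_matches_closed_form(self):
        # deviation of exp(-r^2 / 2 sigma^2) over a centered square ROI can
        # be integrated numerically without rendering
        cfg = sim.VirtualScopeConfig(
            image_shape=(512, 512), vignette_sigma=0.8, seed=21, offset=0.0
        )
        img, truth = sim.render_bath(cfg)
        roi_um = 800.0
        res = uniformity_stats(img, roi_um=roi_um, pixel_size_um=cfg.pixel_size_um)
        sigma = truth.extras["vignette_sigma_um"]
        half = roi_um / 2.0
        ax = np.linspace(-half, half, 801)
        field = np.exp(
            -(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * sigma**2)
        )
        expected = 100.0 * field.std() / field.mean()
        assert res.percent_deviation == pytest.approx(expected, rel=0.10)

    def test_saturated_pixels_excluded_and_counted(self):
        img = np.full((64, 64), 1000.0)
        img[30:34, 30:34] = 32768.0
        res = uniformity_stats(
            img, roi_um=100.0, pixel_size_um=2.77, saturation=32768
        )
        assert res.n_saturated_excluded == 16
        assert "saturated_pixels_excluded" in res.flags
        assert res.percent_deviation == 0.0

    def test_profiles_conserve_image_mean(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(100, 200, size=(64, 96))
        res = uniformity_stats(img, roi_um=50.0, pixel_size_um=2.77)
        assert res.row_profile.mean() == pytest.approx(img.mean())
        assert res.col_profile.mean() == pytest.approx(img.mean())

    def test_percent_deviation_scale_invariant(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(100, 200, size=(64, 64))
        a = uniformity_stats(img, 100.0, 2.77)
        b = uniformity_stats(3.0 * img, 100.0, 2.77)
        assert b.percent_deviation == pytest.approx(a.percent_deviation, rel=1e-12)


class TestFovSummary:
    def test_worked_extent(self):
        m = synthetic_scale_map(lattice_cells(lambda u, v: 2.77))
        s = fov_summary(m)
        assert s.width_mm == pytest.approx(512 * 2.77e-3)  # 1.418 mm
        assert s.height_mm == pytest.approx(512 * 2.77e-3)
        assert s.diagonal_mm == pytest.approx(math.sqrt(2) * 512 * 2.77e-3)  # 2.006
        assert s.area_mm2 == pytest.approx((512 * 2.77e-3) ** 2)
        assert s.predicted_diameter_mm is None

    def test_linear_in_scale(self):
        a = fov_summary(synthetic_scale_map(lattice_cells(lambda u, v: 1.0)))
        b = fov_summary(synthetic_scale_map(lattice_cells(lambda u, v: 2.0)))
        assert b.width_mm == pytest.approx(2.0 * a.width_mm)
        assert b.area_mm2 == pytest.approx(4.0 * a.area_mm2)

    def test_prediction_attached(self, relay_spec, objective_spec):
        m = synthetic_scale_map(lattice_cells(lambda u, v: 2.77))
        s = fov_summary(m, relay_spec, objective_spec)
        assert s.predicted_diameter_mm == pytest.approx(
            predicted_fov_diameter(relay_spec, objective_spec)
        )
        assert s.measured_over_predicted == pytest.approx(
            s.diagonal_mm / s.predicted_diameter_mm
        )
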