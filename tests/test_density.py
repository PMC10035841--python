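"""Registration, kernel density, contours and averaging."""

import numpy as np
import pytest

from blastospat.datatypes import DensityRaster
from blastospat.density import (
    DegenerateLandmarksError,
    LandmarkSet,
    SimilarityTransform,
    average_rasters,
    contour_raster,
    fit_landmark_transform,
    kernel_density,
    surface_mask,
)


def _landmarks(pts):
    return LandmarkSet(
        anterior_pole=tuple(pts[0]), posterior_pole=tuple(pts[1]),
        lateral_left=tuple(pts[2]), lateral_right=tuple(pts[3]),
    )


REF = _landmarks([(5.0, 50.0), (195.0, 50.0), (100.0, 8.0), (100.0, 92.0)])


class TestLandmarkTransform:
    def test_identity_for_identical_landmarks(self):
        tf = fit_landmark_transform(REF, REF)
        assert tf.scale == pytest.approx(1.0)
        assert tf.rotation == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)
        assert tf.residual == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rotation_and_scale(self):
        """Apply a known similarity, then invert it by fitting (1e-9 oracle)."""
        theta = np.deg2rad(30.0)
        truth = SimilarityTransform(scale=1.1, rotation=theta, translation=(13.0, -4.0))
        moving = _landmarks(truth.apply(REF.as_array()))
        tf = fit_landmark_transform(moving, REF)
        inv = truth.inverse()
        assert tf.scale == pytest.approx(inv.scale, abs=1e-9)
        assert tf.rotation == pytest.approx(inv.rotation, abs=1e-9)
        assert np.allclose(tf.translation, inv.translation, atol=1e-9)
        assert tf.residual < 1e-9

    def test_mirrored_landmarks_rejected(self):
        pts = REF.as_array().copy()
        pts[:, 0] = -pts[:, 0]  # reflection
        with pytest.raises(DegenerateLandmarksError):
            fit_landmark_transform(_landmarks(pts), REF)

    def test_collinear_landmarks_rejected(self):
        collinear = _landmarks([(0.0, 0.0), (1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        with pytest.raises(DegenerateLandmarksError):
            fit_landmark_transform(collinear, collinear)

    def test_duplicate_landmarks_rejected(self):
        with pytest.raises(ValueError):
            _landmarks([(0, 0), (0, 0), (1, 0), (0, 1)])


class TestSurfaceMask:
    def test_single_point_gives_disk(self):
        m = surface_mask(np.array([[10.0, 10.0]]), aggregation_distance=30.0)
        assert m.area == pytest.approx(np.pi * 30.0**2, rel=0.01)

    def test_distant_points_give_two_components(self):
        m = surface_mask(np.array([[0.0, 0.0], [100.0, 0.0]]), aggregation_distance=30.0)
        assert m.geom_type == "MultiPolygon"
        assert len(m.geoms) == 2

    def test_close_points_dissolve_into_one(self):
        m = surface_mask(np.array([[0.0, 0.0], [40.0, 0.0]]), aggregation_distance=30.0)
        assert m.geom_type == "Polygon"


class TestKernelDensity:
    def test_zero_points_zero_raster(self):
        r = kernel_density(np.empty((0, 2)), cell_size=1.0, bandwidth=5.0)
        assert np.nansum(r.values) == 0.0

    def test_unit_mass_per_point(self):
        """Σ values × cell² = 1 within 1% for one point in an ample mask."""
        r = kernel_density(np.array([[50.0, 50.0]]), mask=None, cell_size=1.0, bandwidth=12.0)
        assert r.total_mass() == pytest.approx(1.0, rel=0.01)

    def test_mass_conservation_many_points(self, rng):
        pts = rng.uniform(30, 120, size=(80, 2))
        mask = surface_mask(pts, aggregation_distance=25.0)
        r = kernel_density(pts, mask=mask, cell_size=1.0, bandwidth=10.0)
        assert r.total_mass() == pytest.approx(80.0, rel=0.01)

    def test_registration_invariance(self, rng):
        """Densities after a rigid transform of points equal untransformed ones."""
        pts = rng.uniform(20, 80, size=(60, 2))
        tf = SimilarityTransform(scale=1.0, rotation=np.deg2rad(90.0), translation=(200.0, 10.0))
        moved = tf.apply(pts)
        r0 = kernel_density(pts, mask=None, cell_size=1.0, bandwidth=8.0,
                            origin=(0.0, 0.0), shape=(100, 100))
        # evaluate the moved set on the equivalently transformed grid: rotating
        # the frame by 90° maps cell (ix, iy) -> (iy, ix) with x' = 200 - ...
        r1 = kernel_density(moved, mask=None, cell_size=1.0, bandwidth=8.0,
                            origin=(100.0, 10.0), shape=(100, 100))
        # 90° rotation + translation (200,10): (x,y) -> (200-y, 10+x); on the
        # matching grid the rotated raster is the clockwise rotation of r0
        assert np.allclose(r1.values, np.rot90(r0.values, k=-1), atol=1e-9)


class TestContours:
    def test_constant_raster_has_no_contours(self):
        r = DensityRaster(origin=(0, 0), cell_size=1.0, values=np.full((20, 20), 0.004))
        assert contour_raster(r, 0.0005) == {}

    def test_single_point_contours_are_rings_at_analytic_radii(self):
        """Quartic-kernel level sets are circles of radius R√(1−√(v/K0))."""
        bw = 12.0
        r = kernel_density(np.array([[40.0, 40.0]]), mask=None, cell_size=0.5, bandwidth=bw,
                           origin=(0.0, 0.0), shape=(160, 160))
        k0 = 3.0 / (np.pi * bw**2)
        interval = k0 / 8
        contours = contour_raster(r, interval)
        assert len(contours) >= 3
        for level, lines in contours.items():
            assert len(lines) == 1
            ring = lines[0]
            radii = np.sqrt(((ring - 40.0) ** 2).sum(axis=1))
            expected = bw * np.sqrt(1.0 - np.sqrt(level / k0))
            assert np.allclose(radii, expected, atol=0.6)

    def test_interval_default_is_protocol_value(self):
        from blastospat.density import CONTOUR_INTERVAL, STRETCH_HIGH, STRETCH_LOW

        assert CONTOUR_INTERVAL == 0.0005
        assert (STRETCH_LOW, STRETCH_HIGH) == (0.002, 0.0105)


class TestAverage:
    def test_identical_inputs_identity(self, rng):
        vals = rng.uniform(0, 1, size=(10, 10))
        r = DensityRaster(origin=(0, 0), cell_size=2.0, values=vals)
        avg = average_rasters([r, r, r])
        assert np.allclose(avg.values, vals)

    def test_two_rasters_cellwise_mean(self, rng):
        a = rng.uniform(0, 1, size=(8, 8))
        b = rng.uniform(0, 1, size=(8, 8))
        ra = DensityRaster(origin=(0, 0), cell_size=1.0, values=a)
        rb = DensityRaster(origin=(0, 0), cell_size=1.0, values=b)
        assert np.allclose(average_rasters([ra, rb]).values, (a + b) / 2)

    def test_mismatched_grids_rejected(self):
        ra = DensityRaster(origin=(0, 0), cell_size=1.0, values=np.zeros((4, 4)))
        rb = DensityRaster(origin=(0, 0), cell_size=2.0, values=np.zeros((4, 4)))
        with pytest.raises(ValueError):
            average_rasters([ra, rb])

    def test_nine_embryo_average(self, rng):
        """Nine per-embryo rasters (the figure convention) average cellwise."""
        stack = [DensityRaster(origin=(0, 0), cell_size=1.0, values=rng.uniform(0, 1, (6, 6))) for _ in range(9)]
        avg = average_rasters(stack)
        assert np.allclose(avg.values, np.mean([r.values for r in stack], axis=0))
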