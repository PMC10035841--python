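"""Filter chain and iterative-threshold segmentation against constructions."""

import numpy as np
import pytest

from blastospat.datatypes import VoxelStack
from blastospat.segmentation import (
    FilterParams,
    SegmentationParams,
    marker_positive,
    match_to_truth,
    preprocess_stack,
    redirect_intensity,
    segment_nuclei,
)
from blastospat.datatypes import NucleusTruth


def _stack(values, voxel=(0.5, 0.5, 1.0)):
    return VoxelStack(values=np.asarray(values, dtype=float), voxel_size=voxel)


def _sphere_stack(centers_um, radius_um=2.0, shape=(12, 64, 64), voxel=(0.5, 0.5, 1.0), value=1000.0):
    """Binary spheres on a zero background (plus tiny base level)."""
    nz, ny, nx = shape
    dz, dy, dx = voxel[2], voxel[1], voxel[0]
    zz = (np.arange(nz) + 0.5) * dz
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    img = np.zeros(shape)
    for cx, cy, cz in centers_um:
        m = (
            (zz[:, None, None] - cz) ** 2
            + (yy[None, :, None] - cy) ** 2
            + (xx[None, None, :] - cx) ** 2
        ) <= radius_um**2
        img[m] = value
    return _stack(img, voxel)


class TestPreprocess:
    def test_constant_stack_is_fixed_point(self):
        stack = _stack(np.full((6, 20, 20), 37.0))
        out = preprocess_stack(stack, FilterParams(median_radius=1))
        assert np.allclose(out.values, 37.0)

    def test_median_removes_isolated_bright_voxel(self):
        img = np.zeros((9, 15, 15))
        img[4, 7, 7] = 500.0
        out = preprocess_stack(
            _stack(img), FilterParams(median_radius=2, gaussian_radius=1e-6, unsharp_weight=0.5)
        )
        assert out.values[4, 7, 7] == pytest.approx(0.0, abs=1e-6)

    def test_surface_defaults_match_protocol(self):
        d, v = FilterParams.dorsal(), FilterParams.ventral()
        assert (d.unsharp_radius, d.unsharp_weight) == (1.4, 0.7)
        assert (v.unsharp_radius, v.unsharp_weight) == (1.2, 0.6)
        assert d.use_max_filter and not v.use_max_filter
        assert d.median_radius == 2 and d.gaussian_radius == 1.0

    def test_slice_range_subsets(self):
        img = np.random.default_rng(0).uniform(0, 100, size=(10, 12, 12))
        out = preprocess_stack(_stack(img), FilterParams(slice_range=(2, 6)))
        assert out.values.shape == (5, 12, 12)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(unsharp_weight=1.5)

    def test_output_clipped_to_input_range(self, dorsal_stack):
        stack, _ = dorsal_stack
        out = preprocess_stack(stack, FilterParams.dorsal())
        assert out.values.min() >= stack.values.min() - 1e-9
        assert out.values.max() <= stack.values.max() + 1e-9


class TestSegment:
    def test_blank_stack_yields_empty_list(self):
        with pytest.warns(UserWarning):
            out = segment_nuclei(_stack(np.zeros((4, 10, 10))))
        assert out == []

    def test_two_separated_spheres_found_at_truth(self):
        centers = [(10.0, 10.0, 6.0), (20.0, 10.0, 6.0)]
        stack = _sphere_stack(centers, radius_um=2.0)
        recs = segment_nuclei(stack, SegmentationParams(volume_min=15, volume_max=190))
        assert len(recs) == 2
        got = sorted(r.centroid for r in recs)
        for (gx, gy, gz), (cx, cy, cz) in zip(got, centers):
            assert abs(gx - cx) < 0.5 and abs(gy - cy) < 0.5 and abs(gz - cz) < 0.5

    def test_volume_floor_rejects_small_sphere(self):
        # a 10 μm³ sphere (r ≈ 1.34 μm) is below the 15 μm³ floor
        stack = _sphere_stack([(10.0, 10.0, 6.0)], radius_um=1.34)
        recs = segment_nuclei(stack, SegmentationParams(volume_min=15, volume_max=190))
        assert recs == []

    def test_volume_ceiling_rejects_giant_object(self):
        stack = _sphere_stack([(16.0, 16.0, 6.0)], radius_um=4.0)  # ~268 μm³
        recs = segment_nuclei(stack, SegmentationParams(volume_min=15, volume_max=190))
        assert recs == []

    def test_raising_volume_min_never_adds_records(self, dorsal_stack):
        stack, _ = dorsal_stack
        pre = preprocess_stack(stack, FilterParams.dorsal())
        n_prev = None
        for vmin in (15.0, 30.0, 60.0):
            n = len(segment_nuclei(pre, SegmentationParams(volume_min=vmin, volume_max=190)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n

    def test_translation_equivariance(self):
        rngimg = _sphere_stack([(10.0, 12.0, 5.0), (22.0, 20.0, 7.0)], radius_um=2.0)
        shifted = np.roll(rngimg.values, shift=(1, 4, 6), axis=(0, 1, 2))
        recs0 = segment_nuclei(rngimg, SegmentationParams())
        recs1 = segment_nuclei(_stack(shifted, rngimg.voxel_size), SegmentationParams())
        assert len(recs0) == len(recs1) == 2
        d_um = np.array([6 * 0.5, 4 * 0.5, 1 * 1.0])  # (x, y, z)
        got0 = np.sort(np.array([r.centroid for r in recs0]), axis=0)
        got1 = np.sort(np.array([r.centroid for r in recs1]), axis=0)
        assert np.allclose(got1 - got0, d_um, atol=1e-6)

    def test_recall_at_blastoderm_density(self, dorsal_segmentation):
        """Synthetic wt-like stacks segment with ≥90% recall (validation band)."""
        records, truth = dorsal_segmentation
        recall, precision, err = match_to_truth(records, truth, tol_um=2.0)
        assert recall >= 0.90
        assert precision >= 0.90
        assert err < 1.0


class TestRedirect:
    def test_uniform_marker_gives_uniform_means(self, dorsal_segmentation, dorsal_stack):
        records, _ = dorsal_segmentation
        stack, _ = dorsal_stack
        marker = VoxelStack(
            values=np.full(stack.shape, 7.5), voxel_size=stack.voxel_size, channel="ftz"
        )
        out = redirect_intensity(records, marker)
        assert all(r.marker_intensity["ftz"] == pytest.approx(7.5) for r in out)

    def test_painted_subset_and_only_it_crosses_threshold(self, dorsal_segmentation, dorsal_stack):
        from blastospat.synthetic import paint_marker_stack

        records, truth = dorsal_segmentation
        stack, _ = dorsal_stack
        marker = paint_marker_stack(stack, truth, marker="ftz_positive", intensity=200.0, background=5.0)
        out = redirect_intensity(records, marker, channel="ftz")
        # threshold well between the background (5) and the diluted in-nucleus
        # mean (segmented supports extend somewhat beyond the painted nucleus)
        flags = marker_positive(out, "ftz", threshold=60.0)
        # compare against truth markers via matching
        truth_pos = {tuple(np.round(t.center, 1)) for t in truth if t.markers["ftz_positive"]}
        det = np.array([r.centroid for r in out])
        tru = np.array([t.center for t in truth])
        for i, rec in enumerate(out):
            j = int(np.argmin(((tru - det[i]) ** 2).sum(axis=1)))
            if np.linalg.norm(tru[j] - det[i]) < 1.5:
                assert flags[i] == truth[j].markers["ftz_positive"]


class TestMatchToTruth:
    def _truth(self, pts):
        return [NucleusTruth(id=i, center=tuple(p), radius=2.0) for i, p in enumerate(pts)]

    def _records(self, pts):
        from blastospat.segmentation import NucleusRecord

        return [
            NucleusRecord(id=i, centroid=tuple(p), volume=50.0, mean_intensity=100.0, threshold=0.0)
            for i, p in enumerate(pts)
        ]

    def test_identical_sets_score_perfectly(self, rng):
        pts = rng.uniform(0, 50, size=(10, 3))
        recall, precision, err = match_to_truth(self._records(pts), self._truth(pts), 2.0)
        assert recall == precision == 1.0
        assert err == pytest.approx(0.0)

    def test_one_deletion_gives_recall_09(self, rng):
        pts = rng.uniform(0, 100, size=(10, 3))
        recall, _, _ = match_to_truth(self._records(pts[:-1]), self._truth(pts), 2.0)
        assert recall == pytest.approx(0.9)

    def test_matches_brute_force_assignment(self, rng):
        """Hungarian matching equals exhaustive assignment on ≤6 points."""
        from itertools import permutations

        for trial in range(20):
            n = int(rng.integers(2, 7))
            tru = rng.uniform(0, 20, size=(n, 3))
            det = tru + rng.normal(0, 1.0, size=(n, 3))
            tol = 2.0
            d = np.sqrt(((det[:, None, :] - tru[None, :, :]) ** 2).sum(axis=2))
            best = -1
            for perm in permutations(range(n)):
                ok = sum(d[i, perm[i]] <= tol for i in range(n))
                best = max(best, ok)
            recall, _, _ = match_to_truth(self._records(det), self._truth(tru), tol)
            assert recall == pytest.approx(best / n)
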