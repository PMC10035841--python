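"""Generator contracts: determinism, ground-truth fidelity, preset encodings."""

import numpy as np
import pytest

from blastospat import get_preset
from blastospat.datatypes import UM_PER_PX, shoelace_area
from blastospat.presets import PRESETS, DensityField, GenotypePreset
from blastospat.synthetic import (
    HARD_CORE_UM,
    generate_cross_section,
    generate_expression_timecourse,
    generate_membrane_image,
    generate_nuclear_stack,
)


def _flat_preset(density: float) -> GenotypePreset:
    base = PRESETS["wt_late"]
    from dataclasses import replace

    return replace(
        base,
        name="flat",
        dorsal_density=DensityField(base=density, axial_falloff=0.0),
        ventral_density=DensityField(base=density, axial_falloff=0.0),
    )


class TestNuclearStack:
    def test_zero_density_gives_blank_stack_and_empty_truth(self):
        stack, truth = generate_nuclear_stack(_flat_preset(0.0), field_px=(64, 64), n_slices=4, seed=0)
        assert truth == []
        # noise-only stack: nothing approaching nuclear brightness
        assert stack.values.max() < 400

    def test_determinism_bit_identical(self, wt_late):
        a = generate_nuclear_stack(wt_late, field_px=(96, 96), n_slices=6, seed=11)
        b = generate_nuclear_stack(wt_late, field_px=(96, 96), n_slices=6, seed=11)
        assert np.array_equal(a[0].values, b[0].values)
        assert [t.center for t in a[1]] == [t.center for t in b[1]]

    def test_different_seeds_differ(self, wt_late):
        a = generate_nuclear_stack(wt_late, field_px=(96, 96), n_slices=6, seed=1)
        b = generate_nuclear_stack(wt_late, field_px=(96, 96), n_slices=6, seed=2)
        assert not np.array_equal(a[0].values, b[0].values)

    def test_realized_count_tracks_intensity(self):
        """Mean count over seeds within 3 MC SD of the thinned-process expectation.

        The oracle is the direct Monte-Carlo expectation of the same thinned
        hard-core process, estimated from an independent batch of seeds.
        """
        preset = _flat_preset(2.0)
        field = (128, 128)
        counts_a = [
            len(generate_nuclear_stack(preset, field_px=field, n_slices=3, seed=s)[1])
            for s in range(40)
        ]
        counts_b = [
            len(generate_nuclear_stack(preset, field_px=field, n_slices=3, seed=s)[1])
            for s in range(1000, 1040)
        ]
        mean_b = np.mean(counts_b)
        se = np.std(counts_b, ddof=1) / np.sqrt(len(counts_a))
        assert abs(np.mean(counts_a) - mean_b) < 3 * se + 1e-9
        # and the realized mean is close to the un-thinned intensity integral
        area = field[0] * UM_PER_PX * field[1] * UM_PER_PX
        expected = 2.0 / 100.0 * area
        assert np.mean(counts_a) == pytest.approx(expected, rel=0.15)

    def test_wt_late_dorsal_density_peaks_at_midline_center(self, wt_late):
        d = wt_late.dorsal_density
        center = d(0.5, 0.0)
        assert center > d(0.02, 0.0)  # anterior pole
        assert center > d(0.98, 0.0)  # posterior pole
        assert center > d(0.5, 0.95)  # lateral edge

    def test_hard_core_distance_respected(self, dorsal_stack):
        _, truth = dorsal_stack
        pts = np.array([t.center for t in truth])
        from scipy.spatial.distance import pdist

        assert pdist(pts[:, :2]).min() >= HARD_CORE_UM

    def test_calibration_round_trip(self, dorsal_stack):
        stack, truth = dorsal_stack
        centers = np.array([t.center for t in truth])
        back = stack.index_to_um(stack.um_to_index(centers))
        half_voxel = np.array(stack.voxel_size) / 2
        assert np.all(np.abs(back - centers) <= half_voxel.max() + 1e-9)

    def test_field_too_large_rejected(self, wt_late):
        with pytest.raises(ValueError):
            generate_nuclear_stack(wt_late, field_px=(2000, 100), seed=0)


class TestMembraneImage:
    def test_truth_polygons_tile_and_match_shoelace(self, membrane_pair):
        (_, truth), _ = membrane_pair
        total = truth.areas.sum()
        field_area = (260 * UM_PER_PX) ** 2
        assert total == pytest.approx(field_area, rel=1e-6)
        for poly, area in zip(truth.polygons[:20], truth.areas[:20]):
            assert shoelace_area(poly) == pytest.approx(area)

    def test_mean_area_matches_target(self, wt_late):
        """~500 cells at a 40 μm² target: truth mean within 3% (shoelace oracle)."""
        img, truth = generate_membrane_image(wt_late, side="ventral", stage="late", seed=3)
        assert len(truth.polygons) > 400
        assert truth.areas.mean() == pytest.approx(40.0, rel=0.03)

    def test_wt_late_dorsal_target_is_066_of_ventral(self, wt_late):
        assert wt_late.target_area("dorsal", "late") == pytest.approx(0.66 * wt_late.target_area("ventral", "late"))

    def test_mutant_dorsal_areas_scale_wild_type(self):
        wt = get_preset("wt_late")
        assert get_preset("fra").area_dorsal_mean == pytest.approx(1.26 * wt.area_dorsal_mean)
        assert get_preset("gukh").area_dorsal_mean == pytest.approx(1.40 * wt.area_dorsal_mean)

    def test_dorsal_stage_areas_decrease(self, wt_late):
        early = wt_late.target_area("dorsal", "early")
        mid = wt_late.target_area("dorsal", "mid")
        late = wt_late.target_area("dorsal", "late")
        assert early > mid > late
        assert wt_late.target_area("ventral", "early") == wt_late.target_area("ventral", "late")

    def test_gap_free_polygons_are_closed_bright_contours(self, wt_late):
        img, truth = generate_membrane_image(
            wt_late, side="ventral", stage="late", field_px=(160, 160), seed=2, gap_prob=0.0
        )
        # every interior truth vertex chain lies on bright membrane signal
        bright = img > np.percentile(img, 60)
        h, w = img.shape
        checked = 0
        for poly in truth.polygons:
            px = poly / UM_PER_PX
            if px[:, 0].min() < 3 or px[:, 1].min() < 3 or px[:, 0].max() > w - 3 or px[:, 1].max() > h - 3:
                continue
            for x, y in px:
                window = bright[
                    max(0, int(y) - 1) : int(y) + 2, max(0, int(x) - 1) : int(x) + 2
                ]
                assert window.any()
            checked += 1
        assert checked > 10

    def test_determinism(self, wt_late):
        a = generate_membrane_image(wt_late, field_px=(128, 128), seed=5)
        b = generate_membrane_image(wt_late, field_px=(128, 128), seed=5)
        assert np.array_equal(a[0], b[0])
        assert np.allclose(a[1].areas, b[1].areas)

    def test_impossible_target_area_raises(self, wt_late):
        from blastospat.synthetic import GenerationError

        with pytest.raises(GenerationError):
            generate_membrane_image(wt_late, field_px=(16, 16), seed=0)


class TestCrossSection:
    def test_zero_amplitude_gives_flat_profile(self):
        preset = get_preset("gd7")  # DL amplitude 0
        _, truth = generate_cross_section(preset, channel="dl", n_nuclei_per_arc=30, seed=1, noise_frac=0.0)
        assert np.allclose(truth["true_mean"], preset.dl_gradient.baseline)

    def test_noiseless_intensities_equal_gradient(self, wt_late):
        _, truth = generate_cross_section(wt_late, channel="dl", n_nuclei_per_arc=40, seed=2, noise_frac=0.0)
        expected = wt_late.dl_gradient(truth["v"].to_numpy())
        assert np.allclose(truth["rendered_mean"], expected)

    def test_determinism(self, wt_late):
        a = generate_cross_section(wt_late, seed=9)
        b = generate_cross_section(wt_late, seed=9)
        assert np.array_equal(a[0], b[0])


class TestExpressionTimecourse:
    def test_no_planted_genes_means_no_similar_labels(self):
        _, truth = generate_expression_timecourse(n_genes=20, n_planted_similar=0, seed=0)
        assert not truth.similar.any()

    def test_noiseless_planted_genes_score_near_100(self):
        from blastospat.screen import similarity_score

        matrix, truth = generate_expression_timecourse(
            n_genes=30, n_planted_similar=5, noise_sd=0.0, seed=4
        )
        ref = matrix.loc["ref"].to_numpy()
        for gene in matrix.index[truth.similar]:
            s = similarity_score(matrix.loc[gene].to_numpy(), ref)
            assert s > 99.5

    def test_default_pool_size_mirrors_screen(self):
        matrix, truth = generate_expression_timecourse(seed=0)
        assert len(matrix) == 101
        assert truth.annotations.shape[0] == 101

    def test_determinism(self):
        a, _ = generate_expression_timecourse(seed=3)
        b, _ = generate_expression_timecourse(seed=3)
        assert a.equals(b)
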