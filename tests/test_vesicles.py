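import numpy as np
import pytest

from rosella import vesicles as V
from rosella.io import ImageStack
from rosella.synthetic import FieldSpec, NO_NOISE, generate_rosella_field


def brute_force_class(count, small_max, medium_max):
    """Independent three-branch rule used as classification oracle."""
    if count < small_max:
        return "small"
    elif count < medium_max:
        return "medium"
    else:
        return "large"


class TestSizeClassification:
    @pytest.mark.parametrize(
        "scheme_name,cases",
        [
            ("neuronal", {7: "small", 8: "medium", 24: "medium", 25: "large"}),
            ("organoid", {24: "small", 25: "medium", 79: "medium", 80: "large"}),
        ],
    )
    def test_boundary_counts(self, scheme_name, cases):
        scheme = V.get_scheme(scheme_name)
        for count, expected in cases.items():
            assert scheme.classify(count) == expected

    @pytest.mark.parametrize("scheme_name", ["neuronal", "organoid"])
    def test_equivalence_with_brute_force_rule(self, scheme_name, rng):
        scheme = V.get_scheme(scheme_name)
        counts = rng.integers(1, 201, size=10_000)
        mine = [V.classify_count(int(c), scheme) for c in counts]
        oracle = [
            brute_force_class(int(c), scheme.small_max_voxels, scheme.medium_max_voxels)
            for c in counts
        ]
        assert mine == oracle

    def test_nonpositive_count_is_an_error(self):
        with pytest.raises(ValueError):
            V.classify_count(0, V.NEURONAL_SCHEME)

    def test_scheme_constants(self):
        assert (V.NEURONAL_SCHEME.small_max_voxels, V.NEURONAL_SCHEME.medium_max_voxels) == (8, 25)
        assert (V.ORGANOID_SCHEME.small_max_voxels, V.ORGANOID_SCHEME.medium_max_voxels) == (25, 80)
        with pytest.raises(ValueError):
            V.SizeClassScheme("bad", 25, 8)


def two_level_stack(bg=10.0, fg=200.0):
    data = np.full((1, 1, 10, 10), bg, dtype=float)
    data[0, 0, 2:5, 2:5] = fg
    return ImageStack(data, ["DsRed"], 0.0116), data[0] == fg


class TestThresholding:
    def test_otsu_on_separable_bimodal_image_is_exact(self):
        stack, truth = two_level_stack()
        mask = V.threshold_channel(stack, "DsRed", method="otsu")
        assert np.array_equal(mask, truth)

    def test_fixed_threshold_selects_above_only(self):
        data = np.full((1, 1, 2, 2), 50.0)
        data[0, 0, 0, 0] = 150.0
        stack = ImageStack(data, ["DsRed"], 0.0116)
        mask = V.threshold_channel(stack, "DsRed", method="fixed", threshold=100)
        assert mask.sum() == 1 and mask[0, 0, 0]

    def test_constant_channel_under_otsu_warns_and_returns_empty(self):
        stack = ImageStack(np.full((1, 1, 4, 4), 7.0), ["DsRed"], 0.0116)
        with pytest.warns(UserWarning, match="constant"):
            mask = V.threshold_channel(stack, "DsRed", method="otsu")
        assert not mask.any()

    def test_robust_threshold_is_exact_on_noiseless_field(self, noiseless_field):
        stack, gt = noiseless_field
        mask = V.threshold_channel(stack, "DsRed", method="robust")
        assert np.array_equal(mask, gt.red_mask)

    def test_otsu_recovers_truth_on_noiseless_red_channel(self, noiseless_field):
        stack, gt = noiseless_field
        mask = V.threshold_channel(stack, "DsRed", method="otsu")
        assert np.array_equal(mask, gt.red_mask)


class TestDetection:
    def test_empty_red_mask_yields_no_records(self, noiseless_field):
        stack, _ = noiseless_field
        shape = stack.data.shape[1:]
        recs = V.detect_autolysosomes(
            np.zeros(shape, bool), np.zeros(shape, bool), stack
        )
        assert recs == []

    def test_shape_mismatch_is_an_error(self, noiseless_field):
        stack, _ = noiseless_field
        shape = stack.data.shape[1:]
        with pytest.raises(ValueError, match="shapes differ"):
            V.detect_autolysosomes(
                np.zeros(shape, bool), np.zeros((1, 2, 2), bool), stack
            )

    def test_component_inside_green_mask_is_excluded(self):
        data = np.full((2, 1, 12, 12), 10.0)
        data[:, 0, 3:6, 3:6] = 200.0
        stack = ImageStack(data, ["pHluorin", "DsRed"], 0.0116)
        red = data[1] > 100
        recs = V.detect_autolysosomes(red, red.copy(), stack)
        assert recs == []
        recs = V.detect_autolysosomes(red, np.zeros_like(red), stack)
        assert len(recs) == 1 and recs[0].voxel_count == 9

    def test_round_trip_counts_on_noiseless_field(self, noiseless_field):
        stack, gt = noiseless_field
        red = V.threshold_channel(stack, "DsRed", method="otsu")
        green = V.threshold_channel(
            stack, "pHluorin", method="fixed",
            threshold=gt.suggested_thresholds["pHluorin"],
        )
        recs = V.detect_autolysosomes(red, green, stack)
        V.classify_vesicles(recs, V.get_scheme("neuronal"))
        truth = gt.class_counts("red_only")
        assert len(recs) == sum(truth.values())
        for cls in ("small", "medium", "large"):
            assert sum(r.size_class == cls for r in recs) == truth[cls]


class TestCellAreaAndMetrics:
    def test_all_background_field_is_an_error(self):
        stack = ImageStack(np.full((1, 1, 8, 8), 5.0), ["pHluorin"], 0.0116)
        with pytest.raises(ValueError, match="empty cell mask"):
            V.compute_cell_area(stack, "pHluorin", method="fixed", threshold=100)

    def test_cell_area_is_count_times_voxel_area(self):
        mask = np.zeros((1, 120, 100), dtype=bool)
        mask.reshape(-1)[:10_000] = True
        stack = ImageStack(np.zeros((1, 1, 120, 100)), ["pHluorin"], 0.0116)
        assert V.compute_cell_area(stack, "pHluorin", mask=mask) == pytest.approx(116.0)

    def test_hand_arithmetic_example(self):
        recs = [
            V.VesicleRecord(0, "f", 7, 7 * 0.0116, (0, 0, 0), {}),
            V.VesicleRecord(1, "f", 30, 30 * 0.0116, (0, 0, 0), {}),
        ]
        m = V.compute_metrics(recs, 100.0, V.NEURONAL_SCHEME)
        assert m.total_autolysosome_area_per_cell_area == pytest.approx(37 * 0.0116 / 100)
        assert m.autolysosome_count_per_cell_area == pytest.approx(0.02)
        assert m.max_autolysosome_area_um2 == pytest.approx(0.348)
        assert m.count_per_cell_area_by_class["small"] == pytest.approx(0.01)
        assert m.count_per_cell_area_by_class["large"] == pytest.approx(0.01)

    def test_no_vesicles_yields_all_zero_metrics(self):
        m = V.compute_metrics([], 50.0, V.NEURONAL_SCHEME)
        assert m.total_autolysosome_area_per_cell_area == 0
        assert m.autolysosome_count_per_cell_area == 0
        assert m.max_autolysosome_area_um2 == 0

    def test_scale_invariance_of_per_cell_area_metrics(self):
        recs = [V.VesicleRecord(i, "f", 10, 10 * 0.0116, (0, 0, 0), {}) for i in range(4)]
        m1 = V.compute_metrics(list(recs), 200.0, V.NEURONAL_SCHEME)
        doubled = recs + [
            V.VesicleRecord(i + 4, "f", 10, 10 * 0.0116, (0, 0, 0), {}) for i in range(4)
        ]
        m2 = V.compute_metrics(doubled, 400.0, V.NEURONAL_SCHEME)
        assert m2.autolysosome_count_per_cell_area == pytest.approx(
            m1.autolysosome_count_per_cell_area
        )
        assert m2.total_autolysosome_area_per_cell_area == pytest.approx(
            m1.total_autolysosome_area_per_cell_area
        )

    def test_metrics_match_ground_truth_table(self, noiseless_field):
        """Pipeline metrics equal metrics computed from the truth table."""
        stack, gt = noiseless_field
        scheme = V.get_scheme("neuronal")
        red = V.threshold_channel(stack, "DsRed", method="otsu")
        green = V.threshold_channel(
            stack, "pHluorin", method="fixed",
            threshold=gt.suggested_thresholds["pHluorin"],
        )
        recs = V.detect_autolysosomes(red, green, stack)
        cell_area = V.compute_cell_area(stack, "pHluorin", mask=gt.cell_mask)
        m = V.compute_metrics(recs, cell_area, scheme)

        truth = gt.vesicles[gt.vesicles.reporter_state == "red_only"]
        exp_area = truth.voxel_count.sum() * stack.voxel_area_um2
        assert m.total_autolysosome_area_per_cell_area == pytest.approx(exp_area / cell_area)
        assert m.autolysosome_count_per_cell_area == pytest.approx(len(truth) / cell_area)
        assert m.max_autolysosome_area_um2 == pytest.approx(
            truth.voxel_count.max() * stack.voxel_area_um2
        )

    def test_class_partition_sums_to_total(self, noiseless_field):
        stack, gt = noiseless_field
        red = V.threshold_channel(stack, "DsRed", method="otsu")
        recs = V.detect_autolysosomes(red, np.zeros_like(red), stack)
        m = V.compute_metrics(recs, 100.0, V.get_scheme("neuronal"))
        assert sum(m.count_per_cell_area_by_class.values()) == pytest.approx(
            m.autolysosome_count_per_cell_area
        )

    def test_adding_a_vesicle_never_decreases_totals(self):
        recs = [V.VesicleRecord(0, "f", 10, 0.116, (0, 0, 0), {})]
        m1 = V.compute_metrics(list(recs), 100.0, V.NEURONAL_SCHEME)
        recs.append(V.VesicleRecord(1, "f", 3, 0.0348, (0, 0, 0), {}))
        m2 = V.compute_metrics(recs, 100.0, V.NEURONAL_SCHEME)
        assert m2.autolysosome_count_per_cell_area >= m1.autolysosome_count_per_cell_area
        assert m2.total_autolysosome_area_per_cell_area >= m1.total_autolysosome_area_per_cell_area
        assert m2.max_autolysosome_area_um2 >= m1.max_autolysosome_area_um2
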