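import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from rosella.synthetic import (
    NO_NOISE,
    CohortSpec,
    FieldSpec,
    NoiseModel,
    PlacementError,
    _blob_offsets,
    generate_cohort,
    generate_coloc_field,
    generate_mea_recording,
    generate_neurite_field,
    generate_rosella_field,
)

PLANE_8CONN = np.zeros((3, 3, 3), dtype=bool)
PLANE_8CONN[1] = True


def counts(**kw):
    """Shorthand: red_small=5 -> {('red_only','small'): 5}."""
    states = {"red": "red_only", "dual": "dual_positive"}
    return {
        (states[k.split("_")[0]], k.split("_")[1]): v for k, v in kw.items()
    }


class TestRosellaField:
    def test_empty_spec_renders_background_and_cytoplasm_only(self):
        spec = FieldSpec(vesicles_per_class={}, noise=NO_NOISE, seed=0)
        stack, gt = generate_rosella_field(spec)
        assert gt.vesicles.empty
        levels = spec.intensity_levels["pHluorin"]
        assert set(np.unique(stack.channel("pHluorin"))) <= {levels[0], levels[1]}
        assert not gt.red_mask.any()

    def test_requested_sizes_respect_scheme_intervals(self):
        spec = FieldSpec(
            vesicles_per_class=counts(red_small=5, red_large=3),
            noise=NO_NOISE, seed=3,
        )
        _, gt = generate_rosella_field(spec)
        small = gt.vesicles[gt.vesicles.size_class == "small"]
        large = gt.vesicles[gt.vesicles.size_class == "large"]
        assert len(small) == 5 and (small.voxel_count < 8).all()
        assert len(large) == 3 and (large.voxel_count >= 25).all()

    def test_rendered_components_match_ground_truth_sizes(self, noiseless_field):
        """Conservation: noiseless connected components == truth table."""
        stack, gt = noiseless_field
        labels, n = ndimage.label(gt.red_mask, structure=PLANE_8CONN)
        assert n == len(gt.vesicles)
        sizes = np.sort(ndimage.sum_labels(gt.red_mask, labels, np.arange(1, n + 1)))
        assert np.array_equal(sizes, np.sort(gt.vesicles.voxel_count.to_numpy()))
        # the DsRed channel is exactly two-level: vesicles vs elsewhere
        ds = stack.channel("DsRed")
        bg, _, ves = FieldSpec().intensity_levels["DsRed"]
        assert np.array_equal(ds == ves, gt.red_mask)

    def test_same_seed_is_bit_identical(self):
        spec = dict(noise=NoiseModel("gaussian", 0.2), seed=42)
        s1, _ = generate_rosella_field(FieldSpec(**spec))
        s2, _ = generate_rosella_field(FieldSpec(**spec))
        assert np.array_equal(s1.data, s2.data)

    def test_oversubscribed_class_raises_placement_error(self):
        spec = FieldSpec(
            field_shape=(1, 48, 48),
            n_cells=1,
            reporter_fraction=1.0,
            vesicles_per_class=counts(red_large=200),
            noise=NO_NOISE,
            seed=0,
        )
        with pytest.raises(PlacementError, match="red_only/large"):
            generate_rosella_field(spec)

    def test_zero_area_cell_mask_is_an_error(self):
        spec = FieldSpec(n_cells=0, seed=0)
        with pytest.raises(ValueError, match="cell mask"):
            generate_rosella_field(spec)

    def test_poisson_noise_is_supported_and_deterministic(self):
        spec = dict(noise=NoiseModel("poisson", gain=0.5), seed=9)
        s1, _ = generate_rosella_field(FieldSpec(**spec))
        s2, _ = generate_rosella_field(FieldSpec(**spec))
        assert np.array_equal(s1.data, s2.data)
        assert (s1.data >= 0).all()


@settings(max_examples=40, deadline=None)
@given(k=st.integers(min_value=1, max_value=80), seed=st.integers(0, 1000))
def test_blob_offsets_exact_count_and_connectivity(k, seed):
    offs = _blob_offsets(k, np.random.default_rng(seed))
    assert len(offs) == k
    assert len(np.unique(offs, axis=0)) == k
    r = int(np.abs(offs).max()) + 1
    img = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
    img[offs[:, 0] + r, offs[:, 1] + r] = True
    _, n = ndimage.label(img, structure=np.ones((3, 3)))
    assert n == 1


class TestColocField:
    def test_full_overlap_gives_identical_masks(self):
        _, gt = generate_coloc_field(["A", "B"], {("A", "B"): 1.0})
        assert np.array_equal(gt.masks["A"], gt.masks["B"])

    def test_zero_overlap_gives_disjoint_masks(self):
        _, gt = generate_coloc_field(["A", "B"], {("A", "B"): 0.0})
        assert not (gt.masks["A"] & gt.masks["B"]).any()

    def test_quarter_overlap_on_4000_voxels_is_1000_voxels(self):
        _, gt = generate_coloc_field(["A", "B"], {("A", "B"): 0.25}, mask_voxels=4000)
        assert gt.masks["A"].sum() == 4000
        assert (gt.masks["A"] & gt.masks["B"]).sum() == 1000

    def test_triple_fraction_realized(self):
        _, gt = generate_coloc_field(
            ["A", "B", "C"], {("A", "B"): 0.5, ("A", "C"): 0.5},
            triple_fraction=0.2, mask_voxels=4000,
        )
        inter = gt.masks["A"] & gt.masks["B"] & gt.masks["C"]
        assert inter.sum() == 800

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ValueError, match="triple"):
            generate_coloc_field(
                ["A", "B", "C"], {("A", "B"): 0.2, ("A", "C"): 0.2},
                triple_fraction=0.5,
            )
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            generate_coloc_field(["A", "B"], {("A", "B"): 1.5})


class TestMeaGenerator:
    def test_silent_recording_is_pure_noise(self):
        recs, gt = generate_mea_recording(
            n_electrodes=2, duration_s=5, fs=12500, spike_rate=0.0, seed=1
        )
        assert all(len(t) == 0 for t in gt.spike_times.values())
        assert abs(np.std(recs[0].trace) - 1.0) < 0.05

    def test_reproducible_spike_counts(self):
        _, gt1 = generate_mea_recording(n_electrodes=1, duration_s=60, spike_rate=1.0, seed=7)
        _, gt2 = generate_mea_recording(n_electrodes=1, duration_s=60, spike_rate=1.0, seed=7)
        t1 = gt1.spike_times["electrode_01"]
        assert np.array_equal(t1, gt2.spike_times["electrode_01"])
        # Poisson-drawn count at rate 1 Hz over 60 s is plausibly near 60
        assert 20 <= len(t1) <= 120

    def test_refractory_spacing_enforced(self):
        _, gt = generate_mea_recording(
            n_electrodes=1, duration_s=20, spike_rate=5.0, seed=3
        )
        times = gt.spike_times["electrode_01"]
        assert np.diff(times).min() >= 0.002 - 1e-9

    def test_burst_spec_injects_clustered_spikes(self):
        _, gt = generate_mea_recording(
            n_electrodes=1, duration_s=120, spike_rate=0.0,
            burst_spec={"rate_per_min": 5, "n_spikes": 6, "intra_isi_ms": 20},
            seed=2,
        )
        bursts = gt.bursts["electrode_01"]
        assert len(bursts) > 0
        assert len(gt.spike_times["electrode_01"]) == 6 * len(bursts)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            generate_mea_recording(n_electrodes=1, spike_amplitude_sd=0)
        with pytest.raises(ValueError, match="fs"):
            generate_mea_recording(n_electrodes=1, fs=5000)
        with pytest.raises(ValueError, match="duration"):
            generate_mea_recording(n_electrodes=1, duration_s=0)


class TestCohort:
    def test_null_effect_zero_dispersion_gives_identical_groups(self):
        tab, _ = generate_cohort(CohortSpec(pd_effect=1.0, dispersion=0.0))
        wide = tab.pivot_table(
            index=["experiment_id", "timepoint"], columns="condition", values="value"
        )
        pd.testing.assert_series_equal(
            wide["control"], wide["PD"], check_names=False
        )

    def test_deterministic_effect_scales_every_pd_value(self):
        tab, _ = generate_cohort(CohortSpec(pd_effect=0.7, dispersion=0.0))
        ctrl = tab[tab.condition == "control"].value.to_numpy()
        pdv = tab[tab.condition == "PD"].value.to_numpy()
        np.testing.assert_allclose(pdv, 0.7 * ctrl)

    def test_seeded_reproducibility(self):
        t1, _ = generate_cohort(CohortSpec(seed=5))
        t2, _ = generate_cohort(CohortSpec(seed=5))
        pd.testing.assert_frame_equal(t1, t2)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_experiments=1)
        with pytest.raises(ValueError):
            CohortSpec(dispersion=-0.1)


class TestNeuriteField:
    @pytest.mark.parametrize(
        "branches,breaks,expected",
        [(1, 0, 1), (3, 2, 9), (0, 0, 0), (2, 3, 8)],
    )
    def test_fragment_count(self, branches, breaks, expected):
        stack, gt = generate_neurite_field(branches, breaks)
        assert gt.n_fragments == expected
        _, n = ndimage.label(gt.th_mask[0], structure=np.ones((3, 3)))
        assert n == expected
        if expected == 0:
            assert not gt.th_mask.any()
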