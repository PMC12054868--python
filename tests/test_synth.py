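"""Synthetic generator: partitions, sampling statistics, rendering."""

import numpy as np
import pytest

from q3d.synth import (
    CONTROL,
    TREATED,
    Effect,
    SyntheticSpec,
    background_field,
    generate_atlas,
    render_volume,
    sample_objects,
    true_object_mask,
)


class TestGenerateAtlas:
    def test_two_regions_forced_partition(self):
        atlas = generate_atlas((40, 40, 40), 2, seed=0)
        assert set(np.unique(atlas.labels)) == {1, 2}
        assert len(atlas.regions) == 2

    def test_regions_are_connected_boxes(self):
        atlas = generate_atlas((60, 60, 60), 6, seed=1)
        assert set(np.unique(atlas.labels)) == set(range(1, 7))
        for rid in atlas.region_ids:
            vox = np.argwhere(atlas.labels == rid)
            assert len(vox) > 0
            extent = np.prod(vox.max(0) - vox.min(0) + 1)
            assert extent == len(vox)  # axis-aligned box => bbox is full

    def test_deterministic_given_seed(self):
        a = generate_atlas((60, 60, 60), 6, seed=1)
        b = generate_atlas((60, 60, 60), 6, seed=1)
        assert np.array_equal(a.labels, b.labels)
        c = generate_atlas((60, 60, 60), 6, seed=2)
        assert not np.array_equal(a.labels, c.labels)

    def test_single_region_rejected(self):
        with pytest.raises(ValueError, match="n_regions"):
            generate_atlas((40, 40, 40), 1, seed=0)

    def test_more_regions_than_voxels_rejected(self):
        with pytest.raises(ValueError):
            generate_atlas((2, 2, 2), 9, seed=0)


class TestSampleObjects:
    def test_control_unaffected_by_effect_map(self, default_atlas):
        spec = SyntheticSpec(objects_per_region=20.0,
                             effect_map={1: Effect(count=0.5)})
        counts = []
        for s in range(60):
            truth = sample_objects(default_atlas, spec, CONTROL, seed=s)
            counts.append((truth.objects.region_id == 1).sum())
        mean = np.mean(counts)
        se = np.sqrt(20.0 / len(counts))  # Poisson moment oracle
        assert abs(mean - 20.0) < 3 * se

    def test_zero_count_effect_empties_region(self, default_atlas):
        spec = SyntheticSpec(effect_map={1: Effect(count=0.0)})
        truth = sample_objects(default_atlas, spec, TREATED, seed=4)
        assert (truth.objects.region_id == 1).sum() == 0
        assert (truth.objects.region_id != 1).sum() > 0

    def test_poisson_mean_recovered(self, default_atlas):
        spec = SyntheticSpec(objects_per_region=20.0, effect_map={})
        totals = [
            (sample_objects(default_atlas, spec, CONTROL, seed=s).objects
             .region_id == 2).sum()
            for s in range(200)
        ]
        se = np.sqrt(20.0 / 200)
        assert abs(np.mean(totals) - 20.0) < 3 * se

    def test_centers_inside_recorded_region(self, default_atlas, default_spec):
        truth = sample_objects(default_atlas, default_spec, CONTROL, seed=9)
        vs = np.asarray(default_spec.voxel_size_um)
        pos_um = (truth.objects[["z", "y", "x"]].to_numpy() + 0.5) * vs
        idx = np.floor(pos_um / default_atlas.resolution_um).astype(int)
        labels = default_atlas.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.array_equal(labels, truth.objects.region_id.to_numpy())

    def test_radius_floor_one_voxel(self, default_atlas):
        spec = SyntheticSpec(object_radius_mean_um=6.0, object_radius_sd_um=4.0)
        truth = sample_objects(default_atlas, spec, CONTROL, seed=1)
        assert (truth.objects.radius_um >= max(spec.voxel_size_um)).all()

    def test_unknown_effect_region_rejected(self, default_atlas):
        spec = SyntheticSpec(effect_map={99: Effect(count=0.5)})
        with pytest.raises(ValueError, match="unknown region"):
            sample_objects(default_atlas, spec, TREATED, seed=0)


class TestRender:
    def test_background_field_positive_and_bounded(self):
        rng = np.random.default_rng(0)
        f = background_field((40, 40, 40), (5.0, 5.0, 5.0), 0.3, 200.0, rng)
        assert f.min() > 0
        assert np.isclose(f.min(), 0.7) and np.isclose(f.max(), 1.3)

    def test_zero_objects_noiseless_is_background_times_baseline(self, default_atlas):
        spec = SyntheticSpec(objects_per_region=0.0, noise_sd=0.0,
                             volume_shape=(48, 48, 48), effect_map={})
        truth = sample_objects(default_atlas, spec, CONTROL, seed=5)
        assert len(truth) == 0
        img = render_volume(truth, spec, seed=5)
        rng = np.random.default_rng(5)
        field = background_field(
            (48, 48, 48), spec.voxel_size_um, spec.background_amplitude,
            spec.background_length_scale_um, rng,
        )
        assert np.allclose(img.data, (field * spec.baseline).astype(np.float32))

    def test_single_object_noiseless_flat_background(self, default_atlas):
        spec = SyntheticSpec(noise_sd=0.0, background_amplitude=0.0,
                             volume_shape=(48, 48, 48))
        truth = sample_objects(default_atlas, spec, CONTROL, seed=6)
        truth.objects = truth.objects.iloc[:1]
        img = render_volume(truth, spec, seed=6)
        inside = true_object_mask(truth, spec)
        assert np.allclose(img.data[inside], spec.baseline + spec.object_intensity)
        assert np.allclose(img.data[~inside], spec.baseline)

    def test_render_deterministic_and_seed_sensitive(self, default_spec, control_truth):
        a = render_volume(control_truth, default_spec, seed=42)
        b = render_volume(control_truth, default_spec, seed=42)
        c = render_volume(control_truth, default_spec, seed=43)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(noise_sd=-0.1)
    with pytest.raises(ValueError):
        SyntheticSpec(background_length_scale_um=10.0)  # below object radius
    with pytest.raises(ValueError):
        Effect(count=-1.0)


def test_spec_yaml_round_trip():
    spec = SyntheticSpec(seed=5, effect_map={2: Effect(count=0.7, size=1.2)})
    again = SyntheticSpec.from_dict(spec.to_dict())
    assert again == spec
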