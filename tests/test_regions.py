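"""Region aggregation, group summaries, colocalization."""

import numpy as np
import pandas as pd
import pytest

from q3d.atlas import LabelAtlas
from q3d.grids import VoxelMap
from q3d.regions import colocalization_matrix, group_region_summary, region_aggregate
from q3d.stats import GroupDesign, SignificanceMap

from _oracles import loop_colocalization


def two_region_atlas(shape=(8, 8, 8)):
    labels = np.ones(shape, np.int32)
    labels[:, : shape[1] // 2] = 2
    table = pd.DataFrame({"region_id": [1, 2, 3], "name": ["a", "b", "ghost"]})
    return LabelAtlas(labels=labels, regions=table)


def sig_from_sign(sign):
    sign = np.asarray(sign, np.int8)
    mask = sign != 0
    p = VoxelMap(np.where(mask, 0.01, 1.0), quantity="p")
    t = VoxelMap(sign.astype(float), quantity="t")
    return SignificanceMap(mask=mask, sign=sign, p_corrected=p, t=t, alpha=0.05)


class TestRegionAggregate:
    def test_unit_map_sums_to_voxel_counts(self):
        atlas = two_region_atlas()
        table = region_aggregate(VoxelMap(np.ones(atlas.shape)), atlas)
        by_id = table.set_index("region_id")
        assert by_id.loc[1, "sum"] == 256 and by_id.loc[2, "sum"] == 256

    def test_absent_region_reports_zero_not_error(self):
        atlas = two_region_atlas()
        table = region_aggregate(VoxelMap(np.ones(atlas.shape)), atlas)
        ghost = table.set_index("region_id").loc[3]
        assert ghost["n_voxels"] == 0 and ghost["sum"] == 0.0
        assert np.isnan(ghost["mean"])

    def test_half_mask_halves_masked_region_only(self):
        atlas = two_region_atlas()
        sign = np.zeros(atlas.shape, np.int8)
        sign[atlas.labels == 1] = 1
        half = np.argwhere(atlas.labels == 1)[:128]
        sign[half[:, 0], half[:, 1], half[:, 2]] = 0
        table = region_aggregate(
            VoxelMap(np.ones(atlas.shape)), atlas, mask=sig_from_sign(sign)
        ).set_index("region_id")
        assert table.loc[1, "sum"] == 128.0
        assert table.loc[2, "sum"] == 0.0  # unmasked region contributes nothing
        assert table.loc[1, "n_significant"] == 128

    def test_partition_conservation(self):
        atlas = two_region_atlas()
        rng = np.random.default_rng(0)
        m = VoxelMap(rng.uniform(size=atlas.shape))
        table = region_aggregate(m, atlas)
        assert table["sum"].sum() == pytest.approx(m.data.sum())

    def test_nan_voxels_excluded(self):
        atlas = two_region_atlas()
        data = np.ones(atlas.shape)
        data[atlas.labels == 2] = np.nan
        table = region_aggregate(VoxelMap(data, "mean_size"), atlas).set_index("region_id")
        assert table.loc[2, "n_voxels_used"] == 0
        assert table.loc[1, "n_voxels_used"] == 256

    def test_misaligned_map_rejected(self):
        atlas = two_region_atlas()
        with pytest.raises(ValueError, match="aligned"):
            region_aggregate(VoxelMap(np.ones((4, 4, 4))), atlas)


class TestGroupRegionSummary:
    def _tables(self, values):
        return {
            sid: pd.DataFrame(
                {"region_id": [1], "name": ["a"], "sum": [v]}
            )
            for sid, v in values.items()
        }

    def test_identical_samples_zero_sd(self):
        design = GroupDesign(
            sample_ids=["a", "b", "c", "d"],
            groups=["treated", "treated", "control", "control"],
        )
        out = group_region_summary(
            self._tables({"a": 5.0, "b": 5.0, "c": 2.0, "d": 2.0}), design
        )
        assert (out["sd"] == 0).all()

    def test_mean_and_sd_convention(self):
        design = GroupDesign(
            sample_ids=["a", "b", "c", "d"],
            groups=["treated", "treated", "control", "control"],
        )
        out = group_region_summary(
            self._tables({"a": 1.0, "b": 3.0, "c": 7.0, "d": 7.0}), design
        ).set_index("group")
        assert out.loc["treated", "mean"] == 2.0
        assert out.loc["treated", "sd"] == pytest.approx(np.sqrt(2.0))  # n-1

    def test_missing_sample_rejected(self):
        design = GroupDesign(
            sample_ids=["a", "b", "c", "d"],
            groups=["treated", "treated", "control", "control"],
        )
        with pytest.raises(ValueError, match="missing"):
            group_region_summary(self._tables({"a": 1.0}), design)


class TestColocalization:
    def test_disjoint_sets_zero_matrix(self):
        a = np.zeros((6, 6, 6), int)
        b = np.zeros((6, 6, 6), int)
        a[0, 0, 0], b[5, 5, 5] = 1, -1
        m = colocalization_matrix(sig_from_sign(a), sig_from_sign(b))
        assert (m.to_numpy() == 0).all()

    def test_constructed_overlap_counts(self):
        a = np.zeros((10, 10, 10), int)
        b = np.zeros((10, 10, 10), int)
        a.ravel()[:100] = -1          # 100 A-decrease voxels
        b.ravel()[:40] = -1           # 40 of them also B-decrease
        m = colocalization_matrix(sig_from_sign(a), sig_from_sign(b))
        assert m.loc["decrease", "decrease"] == 40
        assert m.loc["decrease", "increase"] == 0

    def test_matches_exhaustive_loop_and_transpose(self):
        rng = np.random.default_rng(1)
        a = rng.choice([-1, 0, 1], size=(12, 12, 12), p=[0.2, 0.6, 0.2])
        b = rng.choice([-1, 0, 1], size=(12, 12, 12), p=[0.3, 0.4, 0.3])
        m = colocalization_matrix(sig_from_sign(a), sig_from_sign(b))
        loop = loop_colocalization(a, b)
        key = {"increase": 1, "decrease": -1}
        for row in m.index:
            for col in m.columns:
                assert m.loc[row, col] == loop[(key[row], key[col])]
        mt = colocalization_matrix(sig_from_sign(b), sig_from_sign(a))
        assert np.array_equal(m.to_numpy(), mt.to_numpy().T)
        total = (np.abs(a) * np.abs(b) > 0).sum()
        assert m.to_numpy().sum() == total

    def test_grid_mismatch_rejected(self):
        a = sig_from_sign(np.zeros((4, 4, 4), int))
        b = sig_from_sign(np.zeros((5, 5, 5), int))
        with pytest.raises(ValueError, match="grid"):
            colocalization_matrix(a, b)
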