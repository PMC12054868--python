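"""Voxel statistics: t-maps, TFCE, permutation FWER, significance masks."""

import numpy as np
import pytest
from scipy import stats as sps

from q3d.grids import VoxelMap
from q3d.stats import (
    GroupDesign,
    TfceParams,
    permutation_correct,
    significance_mask,
    tfce_transform,
    voxel_ttest,
)

from _oracles import brute_force_tfce


def vm(data, q="count"):
    return VoxelMap(np.asarray(data, float), quantity=q)


def maps_from_voxels(values_per_sample, shape=(3, 3, 3), voxel=(1, 1, 1)):
    out = []
    for v in values_per_sample:
        d = np.zeros(shape)
        d[voxel] = v
        out.append(vm(d))
    return out


class TestVoxelTtest:
    def test_matches_textbook_pooled_formula(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = voxel_ttest(maps_from_voxels(a), maps_from_voxels(b))
        # hand computation: means 2 and 5, pooled var 1, se = sqrt(2/3)
        expect_t = (2.0 - 5.0) / np.sqrt(2.0 / 3.0)
        assert t.data[1, 1, 1] == pytest.approx(expect_t)
        assert p.data[1, 1, 1] == pytest.approx(2 * sps.t.sf(abs(expect_t), 4))
        # independent route: scipy's two-sample t-test
        ref = sps.ttest_ind(a, b)
        assert t.data[1, 1, 1] == pytest.approx(ref.statistic)
        assert p.data[1, 1, 1] == pytest.approx(ref.pvalue)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 3, 4)
        t, p = voxel_ttest(maps_from_voxels(a), maps_from_voxels(b), welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert t.data[1, 1, 1] == pytest.approx(ref.statistic)
        assert p.data[1, 1, 1] == pytest.approx(ref.pvalue)

    def test_zero_variance_voxels_masked(self):
        t, p = voxel_ttest(maps_from_voxels([0, 0, 0]), maps_from_voxels([0, 0, 0]))
        assert np.isnan(t.data).all() and np.isnan(p.data).all()

    def test_label_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(1)
        a = [vm(rng.uniform(size=(4, 4, 4))) for _ in range(3)]
        b = [vm(rng.uniform(size=(4, 4, 4))) for _ in range(3)]
        t1, p1 = voxel_ttest(a, b)
        t2, p2 = voxel_ttest(b, a)
        assert np.allclose(t1.data, -t2.data)
        assert np.allclose(p1.data, p2.data)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            voxel_ttest(maps_from_voxels([1.0]), maps_from_voxels([1.0, 2.0]))


class TestTfce:
    def test_zero_map_is_zero(self):
        out = tfce_transform(vm(np.zeros((8, 8, 8)), "t"))
        assert not out.data.any()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        stat = rng.standard_normal((12, 12, 12))
        params = TfceParams()
        ours = tfce_transform(vm(stat, "t"), params).data
        oracle = brute_force_tfce(stat, params.E, params.H, params.n_steps)
        assert np.allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_single_peak_closed_form(self):
        stat = np.zeros((9, 9, 9))
        stat[4, 4, 4] = 2.0
        out = tfce_transform(vm(stat, "t"), TfceParams(dh_frac=0.001))
        # extent 1 at every height: integral of h^2 dh over (0, v) = v^3/3
        assert out.data[4, 4, 4] == pytest.approx(2.0**3 / 3, rel=5e-3)

    def test_sign_split(self):
        stat = np.zeros((9, 9, 9))
        stat[2, 2, 2], stat[6, 6, 6] = 3.0, -3.0
        out = tfce_transform(vm(stat, "t")).data
        assert out[2, 2, 2] > 0 and out[6, 6, 6] < 0
        assert out[2, 2, 2] == pytest.approx(-out[6, 6, 6])

    def test_pointwise_increase_never_decreases_tfce(self):
        rng = np.random.default_rng(3)
        stat = np.abs(rng.standard_normal((10, 10, 10)))
        stat[5, 5, 5] = stat.max() + 1.0  # fixed peak keeps the dh grid shared
        bumped = stat.copy()
        mask = rng.uniform(size=stat.shape) < 0.3
        bumped[mask] += rng.uniform(0, 0.5, size=int(mask.sum()))
        bumped[5, 5, 5] = stat[5, 5, 5]
        a = tfce_transform(vm(stat, "t")).data
        b = tfce_transform(vm(bumped, "t")).data
        assert (b - a).min() > -1e-9

    def test_nan_voxels_contribute_nothing(self):
        stat = np.full((6, 6, 6), np.nan)
        stat[3, 3, 3] = 1.0
        out = tfce_transform(vm(stat, "t")).data
        assert np.isfinite(out).all()
        assert out[3, 3, 3] > 0


class TestPermutationCorrect:
    def test_exhaustive_two_vs_two_min_p(self):
        rng = np.random.default_rng(4)
        base = [vm(rng.uniform(size=(5, 5, 5)) * 0.01) for _ in range(4)]
        for m in base[:2]:
            m.data[2, 2, 2] += 10.0  # overwhelming treated effect
        design = GroupDesign(
            sample_ids=["t1", "t2", "c1", "c2"],
            groups=["treated", "treated", "control", "control"],
        )
        res = permutation_correct(base, design, TfceParams(seed=0))
        assert res.exhaustive and res.n_perm_used == 5  # C(4,2) - identity
        # the label-swapped relabeling negates t, so its max |TFCE| always
        # ties the observed one: the smallest achievable two-sided
        # corrected p over 6 relabelings (incl. identity) is 2/6
        assert res.p_corrected.data.min() == pytest.approx(2.0 / 6.0)
        assert res.p_corrected.data[2, 2, 2] == pytest.approx(2.0 / 6.0)

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(5)
        shared = [rng.uniform(size=(6, 6, 6)) for _ in range(3)]
        maps = [vm(d) for d in shared] + [vm(d.copy()) for d in shared]
        design = GroupDesign(
            sample_ids=[f"s{i}" for i in range(6)],
            groups=["treated"] * 3 + ["control"] * 3,
        )
        res = permutation_correct(maps, design, TfceParams(seed=1))
        sig = significance_mask(res.p_corrected, res.t, 0.05)
        assert sig.n_significant == 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        maps = [vm(rng.uniform(size=(6, 6, 6))) for _ in range(10)]
        design = GroupDesign(
            sample_ids=[f"s{i}" for i in range(10)],
            groups=["treated"] * 5 + ["control"] * 5,
        )
        params = TfceParams(n_perm=50, seed=7)  # C(10,5)-1 = 251 > 50: sampled
        a = permutation_correct(maps, design, params)
        b = permutation_correct(maps, design, params)
        assert not a.exhaustive
        assert np.array_equal(a.p_corrected.data, b.p_corrected.data)
        assert np.array_equal(a.null_max_tfce, b.null_max_tfce)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="two groups"):
            GroupDesign(sample_ids=["a", "b"], groups=["x", "x"])
        with pytest.raises(ValueError, match="at least 2"):
            GroupDesign(
                sample_ids=["a", "b", "c"], groups=["treated", "control", "control"]
            )


class TestSignificanceMask:
    def test_all_ones_p_empty_mask(self):
        p = vm(np.ones((4, 4, 4)), "p")
        t = vm(np.ones((4, 4, 4)), "t")
        assert significance_mask(p, t, 0.05).n_significant == 0

    def test_boundary_alpha_not_significant(self):
        p = vm(np.full((4, 4, 4), 0.05), "p")
        t = vm(np.ones((4, 4, 4)), "t")
        assert significance_mask(p, t, 0.05).n_significant == 0

    def test_sign_follows_t(self):
        p = vm(np.full((4, 4, 4), 0.01), "p")
        tdata = np.ones((4, 4, 4))
        tdata[0] = -1.0
        sig = significance_mask(p, vm(tdata, "t"), 0.05)
        assert (sig.sign[0] == -1).all()
        assert (sig.sign[1:] == 1).all()
        assert not np.any((sig.sign != 0) & ~sig.mask)
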