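"""Voxel-wise two-group statistics with TFCE and permutation FWER.

The comparison runs on per-sample heatmaps: a two-sided two-sample
t-test at every atlas voxel (treated minus control orientation), a
threshold-free cluster enhancement (TFCE) transform of the t-map, and
family-wise error control by the max-statistic permutation scheme —
group labels are permuted, the maximum |TFCE| of each permuted map forms
the null distribution, and each voxel's corrected p is the add-one
fraction of permutation maxima at or above its observed |TFCE|.  When
few samples make exhaustive relabeling cheaper than random sampling, all
distinct relabelings are used and the test is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from ._tfce import tfce_array
from .grids import VoxelMap


def _neighbor_offsets(connectivity: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    offs = np.argwhere(structure) - 1
    return offs[np.any(offs != 0, axis=1)].astype(np.int64)


@dataclass
class GroupDesign:
    """Assignment of samples to the two comparison groups."""

    sample_ids: list[str]
    groups: list[str]
    treated_label: str = "treated"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must align")
        levels = set(self.groups)
        if levels != {self.treated_label, self.control_label}:
            raise ValueError(
                f"design must contain exactly the two groups "
                f"{self.treated_label!r} and {self.control_label!r}, got {sorted(levels)}"
            )
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def treated_mask(self) -> np.ndarray:
        return np.array([g == self.treated_label for g in self.groups])

    @property
    def n_treated(self) -> int:
        return sum(g == self.treated_label for g in self.groups)

    @property
    def n_control(self) -> int:
        return sum(g == self.control_label for g in self.groups)


@dataclass(frozen=True)
class TfceParams:
    """TFCE and permutation-test settings.

    ``E`` and ``H`` are the extent and height exponents (standard
    defaults 0.5 and 2); ``dh_frac`` sets the integration step as a
    fraction of the map's maximum |statistic| (0.01 means 100 steps);
    ``n_perm`` caps the number of relabelings (exhaustive enumeration is
    used automatically when it needs no more than that); ``alpha`` is
    the significance level for the final mask.
    """

    E: float = 0.5
    H: float = 2.0
    dh_frac: float = 0.01
    connectivity: int = 26
    n_perm: int = 1000
    seed: int = 0
    alpha: float = 0.05
    welch: bool = False

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if not 0 < self.dh_frac <= 1:
            raise ValueError("dh_frac must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")

    @property
    def n_steps(self) -> int:
        return int(round(1.0 / self.dh_frac))


@dataclass
class SignificanceMap:
    """Binary significant mask with per-voxel effect direction.

    ``sign`` is +1 where the treated group increases, -1 where it
    decreases, 0 off the mask.
    """

    mask: np.ndarray
    sign: np.ndarray
    p_corrected: VoxelMap
    t: VoxelMap
    alpha: float

    def __post_init__(self) -> None:
        if np.any((self.sign != 0) & ~self.mask):
            raise ValueError("sign must be zero off the significant mask")

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())

    @property
    def increase_mask(self) -> np.ndarray:
        return self.sign > 0

    @property
    def decrease_mask(self) -> np.ndarray:
        return self.sign < 0


# ---------------------------------------------------------------------------
# t maps
# ---------------------------------------------------------------------------

def _stack(maps) -> np.ndarray:
    arrs = [m.data if isinstance(m, VoxelMap) else np.asarray(m) for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"heatmaps are not aligned: shapes {sorted(shapes)}")
    return np.stack([a.astype(np.float64, copy=False).ravel() for a in arrs])


def _t_from_sums(s1, ss1, n1, s2, ss2, n2, welch: bool):
    """Two-sample t from per-group sums and sums of squares (flat arrays)."""
    m1, m2 = s1 / n1, s2 / n2
    v1 = np.maximum(ss1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(ss2 - n2 * m2**2, 0.0) / (n2 - 1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    bad = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    t[bad] = np.nan
    return t, df, bad


def voxel_ttest(
    maps_treated,
    maps_control,
    welch: bool = False,
) -> tuple[VoxelMap, VoxelMap]:
    """Two-sided two-sample t-test at every voxel (treated - control).

    Voxels with zero pooled variance (including all-zero voxels in both
    groups) are masked out: t and p are NaN there.
    """
    a = _stack(maps_treated)
    b = _stack(maps_control)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    shape = (maps_treated[0].data if isinstance(maps_treated[0], VoxelMap)
             else np.asarray(maps_treated[0])).shape
    t, df, bad = _t_from_sums(
        a.sum(0), (a**2).sum(0), a.shape[0],
        b.sum(0), (b**2).sum(0), b.shape[0], welch,
    )
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t), df)
    p[bad] = np.nan
    res = maps_treated[0].resolution_um if isinstance(maps_treated[0], VoxelMap) else None
    kwargs = {} if res is None else {"resolution_um": res}
    return (
        VoxelMap(t.reshape(shape), quantity="t", **kwargs),
        VoxelMap(p.reshape(shape), quantity="p", **kwargs),
    )


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def tfce_transform(stat: VoxelMap, params: TfceParams | None = None) -> VoxelMap:
    """Signed TFCE of a (possibly NaN-masked) statistic map."""
    params = params or TfceParams()
    out = tfce_array(
        stat.data, params.E, params.H, params.n_steps,
        _neighbor_offsets(params.connectivity),
    )
    vm = stat.like(out, quantity="tfce")
    vm.meta.update(E=params.E, H=params.H, n_steps=params.n_steps)
    return vm


# ---------------------------------------------------------------------------
# Permutation FWER correction
# ---------------------------------------------------------------------------

def _relabelings(design: GroupDesign, params: TfceParams, rng: np.random.Generator):
    """Treated-index sets to evaluate (identity excluded) and whether the
    enumeration is exhaustive."""
    n = len(design.groups)
    k = design.n_treated
    from math import comb

    observed = tuple(np.flatnonzero(design.treated_mask).tolist())
    if comb(n, k) - 1 <= params.n_perm:
        sets = [c for c in combinations(range(n), k) if c != observed]
        return sets, True
    sets = []
    for _ in range(params.n_perm):
        sets.append(tuple(rng.permutation(n)[:k].tolist()))
    return sets, False


@dataclass
class PermutationResult:
    t: VoxelMap
    tfce: VoxelMap
    p_corrected: VoxelMap
    null_max_tfce: np.ndarray
    n_perm_used: int
    exhaustive: bool


def permutation_correct(
    maps,
    design: GroupDesign,
    params: TfceParams | None = None,
) -> PermutationResult:
    """FWER-corrected p-values by max-TFCE permutation of group labels.

    ``maps`` is one heatmap per sample, aligned with ``design``.  For
    every relabeling, the permuted t-map is TFCE-enhanced and its
    maximum |TFCE| recorded; corrected p at a voxel is
    ``(1 + #{max >= |TFCE_obs|}) / (1 + n_perm)``.  Deterministic given
    ``params.seed``.
    """
    params = params or TfceParams()
    X = _stack(maps)
    if X.shape[0] != len(design.groups):
        raise ValueError("number of maps must match the design")
    shape = (maps[0].data if isinstance(maps[0], VoxelMap) else np.asarray(maps[0])).shape
    from .grids import ATLAS_RESOLUTION_UM

    res_um = maps[0].resolution_um if isinstance(maps[0], VoxelMap) else ATLAS_RESOLUTION_UM

    n = X.shape[0]
    S = X.sum(0)
    SS = (X**2).sum(0)
    offs = _neighbor_offsets(params.connectivity)

    def t_for(treated_idx: np.ndarray) -> np.ndarray:
        sel = np.zeros(n, dtype=bool)
        sel[list(treated_idx)] = True
        n1 = int(sel.sum())
        s1 = X[sel].sum(0)
        ss1 = (X[sel] ** 2).sum(0)
        t, _, _ = _t_from_sums(s1, ss1, n1, S - s1, SS - ss1, n - n1, params.welch)
        return t.reshape(shape)

    obs_idx = np.flatnonzero(design.treated_mask)
    t_obs = t_for(obs_idx)
    tfce_obs = tfce_array(t_obs, params.E, params.H, params.n_steps, offs)

    rng = np.random.default_rng(params.seed)
    sets, exhaustive = _relabelings(design, params, rng)
    null_max = np.empty(len(sets), dtype=np.float64)
    for i, idx in enumerate(sets):
        t_perm = tfce_array(t_for(np.asarray(idx)), params.E, params.H,
                            params.n_steps, offs)
        null_max[i] = np.abs(t_perm).max()

    sorted_max = np.sort(null_max)
    obs_abs = np.abs(tfce_obs).ravel()
    # count of permutation maxima >= observed
    ge = len(sets) - np.searchsorted(sorted_max, obs_abs, side="left")
    p = (1.0 + ge) / (1.0 + len(sets))
    p = p.reshape(shape)
    p[np.isnan(t_obs)] = 1.0

    mk = lambda d, q: VoxelMap(d, quantity=q, resolution_um=res_um)
    return PermutationResult(
        t=mk(t_obs, "t"),
        tfce=mk(tfce_obs, "tfce"),
        p_corrected=mk(p, "p"),
        null_max_tfce=null_max,
        n_perm_used=len(sets),
        exhaustive=exhaustive,
    )


def significance_mask(
    p_corrected: VoxelMap,
    t: VoxelMap,
    alpha: float = 0.05,
) -> SignificanceMap:
    """Binarize corrected p at ``alpha`` (strict) with the t-map's sign."""
    if p_corrected.shape != t.shape:
        raise ValueError("p and t maps must share a grid")
    with np.errstate(invalid="ignore"):
        mask = p_corrected.data < alpha
    mask &= ~np.isnan(t.data)
    sign = np.zeros(t.shape, dtype=np.int8)
    sign[mask] = np.sign(t.data[mask]).astype(np.int8)
    return SignificanceMap(
        mask=mask, sign=sign, p_corrected=p_corrected, t=t, alpha=alpha
    )
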