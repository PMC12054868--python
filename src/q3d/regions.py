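"""Region-level aggregation and significance-map colocalization.

Voxel maps are rolled up into anatomically labeled regions, optionally
masked to the voxels that survived FWER correction; per-sample region
values are then summarized per group (mean ± SD).  Two signed
significance maps (e.g. plaque count vs microglia volume) are compared
with a 2x2 colocalization matrix counting voxels simultaneously
significant in both, split by direction of effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .grids import VoxelMap
from .stats import GroupDesign, SignificanceMap

COLOC_LEVELS = ("increase", "decrease")


def region_aggregate(
    vmap: VoxelMap,
    atlas: LabelAtlas,
    mask: SignificanceMap | None = None,
) -> pd.DataFrame:
    """Per-region sums and means of a voxel map.

    With a significance mask, aggregation is restricted to the region's
    significant voxels (``region ∩ mask``); signed significant-voxel
    counts are reported either way.  Regions listed in the atlas table
    but absent from the label volume come back with zero voxels.
    NaN map voxels (e.g. undefined mean sizes) are excluded.
    """
    if vmap.shape != atlas.shape:
        raise ValueError("map and atlas are not aligned")
    labels = atlas.labels
    data = vmap.data.astype(np.float64, copy=False)
    valid = ~np.isnan(data)
    sel = valid if mask is None else (valid & mask.mask)

    nmax = max(atlas.region_ids, default=0) + 1
    lab_sel = labels[sel]
    w = data[sel]
    sums = np.bincount(lab_sel, weights=w, minlength=nmax)
    n_used = np.bincount(lab_sel, minlength=nmax)
    n_region = np.bincount(labels.ravel(), minlength=nmax)
    if mask is not None:
        n_sig = np.bincount(labels[mask.mask], minlength=nmax)
        n_up = np.bincount(labels[mask.increase_mask], minlength=nmax)
        n_dn = np.bincount(labels[mask.decrease_mask], minlength=nmax)
    else:
        n_sig = n_up = n_dn = np.zeros(nmax, dtype=np.int64)

    rows = []
    for rid in atlas.region_ids:
        rows.append(
            {
                "region_id": rid,
                "name": atlas.region_name(rid),
                "n_voxels": int(n_region[rid]),
                "n_voxels_used": int(n_used[rid]),
                "n_significant": int(n_sig[rid]),
                "n_increase": int(n_up[rid]),
                "n_decrease": int(n_dn[rid]),
                "sum": float(sums[rid]),
                "mean": float(sums[rid] / n_used[rid]) if n_used[rid] else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["quantity"] = vmap.quantity
    out.attrs["masked"] = mask is not None
    return out


def group_region_summary(
    per_sample: dict[str, pd.DataFrame],
    design: GroupDesign,
    value: str = "sum",
) -> pd.DataFrame:
    """Group mean ± SD of a per-region value across samples.

    ``per_sample`` maps sample id to its :func:`region_aggregate` table;
    SD uses the n-1 convention.
    """
    missing = set(design.sample_ids) - set(per_sample)
    if missing:
        raise ValueError(f"missing region tables for samples {sorted(missing)}")
    frames = []
    for sid, group in zip(design.sample_ids, design.groups):
        t = per_sample[sid][["region_id", "name", value]].copy()
        t["sample_id"] = sid
        t["group"] = group
        frames.append(t)
    long = pd.concat(frames, ignore_index=True)
    out = (
        long.groupby(["region_id", "name", "group"])[value]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def colocalization_matrix(
    sig_a: SignificanceMap,
    sig_b: SignificanceMap,
) -> pd.DataFrame:
    """2x2 overlap counts between two signed significance maps.

    Rows are map A's increase/decrease sets, columns map B's; each entry
    counts voxels carrying both signs.  The matrix of (B, A) is the
    transpose of (A, B).
    """
    if sig_a.sign.shape != sig_b.sign.shape:
        raise ValueError("significance maps are not on the same grid")
    sets_a = {"increase": sig_a.increase_mask, "decrease": sig_a.decrease_mask}
    sets_b = {"increase": sig_b.increase_mask, "decrease": sig_b.decrease_mask}
    data = {
        col: [int((sets_a[row] & sets_b[col]).sum()) for row in COLOC_LEVELS]
        for col in COLOC_LEVELS
    }
    return pd.DataFrame(data, index=list(COLOC_LEVELS))
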