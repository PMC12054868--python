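"""Atlas space: label volumes, per-sample transforms, and voxel maps.

Detections live on the native acquisition grid (anisotropic, a few µm per
voxel).  Group statistics happen on a common isotropic atlas grid
(25 µm per voxel side by default, the resolution of standard reference
parcellations).  This module maps native coordinates into atlas space and
accumulates per-voxel count, size and volume maps.

Coordinate conventions (fixed, to avoid half-voxel drift between
samples): indices are 0-based; the physical position of voxel ``i`` is
``(i + 0.5) * voxel_size`` (voxel-centre convention); atlas binning is
``floor(position / resolution)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .grids import ATLAS_RESOLUTION_UM, VoxelMap

if TYPE_CHECKING:  # pragma: no cover
    from .detect import ObjectTable

UM3_PER_MM3 = 1e9


@dataclass
class LabelAtlas:
    """3D integer parcellation with a region-name table.

    Label 0 means outside the brain; every nonzero label that occurs in
    ``labels`` must have a row in ``regions`` (columns ``region_id``,
    ``name``, optionally ``parent``).
    """

    labels: np.ndarray
    regions: pd.DataFrame
    resolution_um: float = ATLAS_RESOLUTION_UM

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integer")
        for col in ("region_id", "name"):
            if col not in self.regions.columns:
                raise ValueError(f"region table missing column {col!r}")
        present = set(np.unique(self.labels).tolist()) - {0}
        known = set(int(r) for r in self.regions["region_id"])
        orphan = present - known
        if orphan:
            raise ValueError(f"labels {sorted(orphan)} missing from region table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def region_ids(self) -> list[int]:
        return [int(r) for r in self.regions["region_id"]]

    def region_name(self, region_id: int) -> str:
        row = self.regions.loc[self.regions["region_id"] == region_id, "name"]
        if row.empty:
            raise KeyError(f"unknown region id {region_id}")
        return str(row.iloc[0])

    def empty_map(self, quantity: str = "count", dtype=np.float64) -> VoxelMap:
        return VoxelMap(
            data=np.zeros(self.shape, dtype=dtype),
            quantity=quantity,
            resolution_um=self.resolution_um,
        )


@dataclass
class SampleTransform:
    """Affine map from native physical coordinates to atlas physical
    coordinates, both in µm, acting on ``(z, y, x)`` triples."""

    matrix: np.ndarray = field(
        default_factory=lambda: np.eye(4, dtype=np.float64)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform must be a 4x4 matrix")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform is not invertible")

    @classmethod
    def identity(cls) -> "SampleTransform":
        return cls()

    @classmethod
    def translation(cls, shift_um) -> "SampleTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(shift_um, dtype=float)
        return cls(matrix=m)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(4)))

    def apply(self, points_um: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` array of physical positions."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=np.float64))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def to_file(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def from_file(cls, path) -> "SampleTransform":
        return cls(matrix=np.loadtxt(Path(path)))


# ---------------------------------------------------------------------------
# Coordinate mapping.
# ---------------------------------------------------------------------------

def native_to_atlas_indices(
    coords_vox: np.ndarray,
    voxel_size_um,
    transform: SampleTransform | None = None,
    resolution_um: float = ATLAS_RESOLUTION_UM,
) -> np.ndarray:
    """Map ``(n, 3)`` native voxel coordinates to integer atlas indices.

    Positions use the voxel-centre convention; binning is ``floor``.
    Indices may fall outside any particular atlas — bounds are the
    caller's concern (see :func:`bin_counts`).
    """
    coords = np.atleast_2d(np.asarray(coords_vox, dtype=np.float64))
    vs = np.asarray(voxel_size_um, dtype=np.float64)
    pos = (coords + 0.5) * vs
    if transform is not None and not transform.is_identity:
        pos = transform.apply(pos)
    return np.floor(pos / resolution_um).astype(np.int64)


def to_atlas_voxel(
    coord_vox,
    voxel_size_um,
    transform: SampleTransform | None = None,
    resolution_um: float = ATLAS_RESOLUTION_UM,
) -> tuple[int, int, int]:
    """Single-coordinate convenience wrapper around
    :func:`native_to_atlas_indices`."""
    idx = native_to_atlas_indices(
        np.asarray(coord_vox, dtype=float)[None, :], voxel_size_um,
        transform, resolution_um,
    )[0]
    return int(idx[0]), int(idx[1]), int(idx[2])


def bin_counts(
    indices: np.ndarray,
    shape: tuple[int, int, int],
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Accumulate (weighted) counts of integer indices on a grid.

    Returns the accumulation array and the number of indices rejected
    for lying outside the grid.
    """
    indices = np.atleast_2d(indices)
    inside = np.all((indices >= 0) & (indices < np.asarray(shape)), axis=1)
    n_outside = int((~inside).sum())
    out = np.zeros(shape, dtype=np.float64)
    if indices[inside].size:
        flat = np.ravel_multi_index(tuple(indices[inside].T), shape)
        w = None if weights is None else np.asarray(weights, dtype=np.float64)[inside]
        np.add.at(out.ravel(), flat, 1.0 if w is None else w)
    return out, n_outside


# ---------------------------------------------------------------------------
# Map builders.
# ---------------------------------------------------------------------------

def count_map(
    objects: "ObjectTable",
    atlas: LabelAtlas,
    transform: SampleTransform | None = None,
) -> VoxelMap:
    """Per-voxel object count: each object contributes 1 at the atlas
    voxel containing its centroid.  Objects mapping outside the atlas are
    counted in ``meta['n_outside']``, never silently dropped."""
    idx = native_to_atlas_indices(
        objects.centroids, objects.voxel_size_um, transform, atlas.resolution_um
    )
    data, n_outside = bin_counts(idx, atlas.shape)
    vm = atlas.empty_map("count")
    vm.data = data
    vm.meta["n_outside"] = n_outside
    vm.meta["sample_id"] = objects.sample_id
    return vm


def size_maps(
    objects: "ObjectTable",
    atlas: LabelAtlas,
    transform: SampleTransform | None = None,
) -> tuple[VoxelMap, VoxelMap]:
    """Summed object size (µm³) and object count per atlas voxel.

    Object size is its native voxel count times the native voxel volume;
    it accumulates at the centroid's atlas voxel.  Dividing the two maps
    (after ROI smoothing) gives the mean object size."""
    idx = native_to_atlas_indices(
        objects.centroids, objects.voxel_size_um, transform, atlas.resolution_um
    )
    sizes_um3 = objects.table["volume_voxels"].to_numpy(float) * objects.voxel_volume_um3
    size_data, n_out = bin_counts(idx, atlas.shape, weights=sizes_um3)
    count_data, _ = bin_counts(idx, atlas.shape)
    size_vm = atlas.empty_map("size_sum")
    size_vm.data = size_data
    size_vm.meta["n_outside"] = n_out
    count_vm = atlas.empty_map("count")
    count_vm.data = count_data
    count_vm.meta["n_outside"] = n_out
    for vm in (size_vm, count_vm):
        vm.meta["sample_id"] = objects.sample_id
    return size_vm, count_vm


def volume_map(
    objects: "ObjectTable",
    atlas: LabelAtlas,
    transform: SampleTransform | None = None,
) -> VoxelMap:
    """Total object volume per atlas voxel, in mm³.

    Every member foreground voxel (not just the centroid) maps to atlas
    space; assuming constant density over the detected voxels, the atlas
    voxel value is the number of mapped native voxels times the native
    voxel volume."""
    if objects.members is None:
        raise ValueError("volume_map needs member-voxel lists (run detect with members)")
    vm = atlas.empty_map("volume_mm3")
    n_outside = 0
    if len(objects.members):
        all_members = np.concatenate([m for m in objects.members]) if objects.members else None
        if all_members is not None and all_members.size:
            idx = native_to_atlas_indices(
                all_members.astype(np.float64), objects.voxel_size_um,
                transform, atlas.resolution_um,
            )
            data, n_outside = bin_counts(idx, atlas.shape)
            vm.data = data * (objects.voxel_volume_um3 / UM3_PER_MM3)
    vm.meta["n_outside"] = n_outside
    vm.meta["sample_id"] = objects.sample_id
    return vm
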