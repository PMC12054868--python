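"""Voxel-based object detection on restored ratio images.

Detection follows the threshold-and-label recipe: binarize the restored
(dimensionless) intensity at a fixed ratio threshold, identify connected
foreground components as individual objects, then discard components
that are too small or too dim (minimum volume and minimum peak ratio) to
eliminate noise artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ImageStack

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds.

    ``intensity_threshold`` (default 1.8) is applied to the restored
    ratio image, inclusively (a voxel exactly at the threshold is
    foreground).  ``min_volume`` (voxels) and ``min_peak`` (ratio) are
    the artifact filters; connectivity is the 3D neighbourhood used for
    component labeling.
    """

    intensity_threshold: float = 1.8
    min_volume: int = 4
    min_peak: float = 2.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not self.intensity_threshold > 1:
            raise ValueError("intensity_threshold must exceed 1 (the flat-tissue ratio)")
        if self.min_volume < 1:
            raise ValueError("min_volume must be >= 1 voxel")
        if self.min_peak < self.intensity_threshold:
            raise ValueError("min_peak must be >= intensity_threshold")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class ObjectTable:
    """Detected objects of one sample.

    ``table`` columns: ``sample_id, object_id, z, y, x, volume_voxels,
    peak_ratio`` with centroids in 0-based native voxel coordinates
    (voxel-centre convention).  ``members[i]`` is the ``(n_i, 3)`` array
    of member voxel indices of row ``i`` (needed for volume maps).
    """

    table: pd.DataFrame
    voxel_size_um: tuple[float, float, float]
    sample_id: str = "sample"
    members: list[np.ndarray] | None = None

    COLUMNS = ("sample_id", "object_id", "z", "y", "x", "volume_voxels", "peak_ratio")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"object table missing columns {sorted(missing)}")
        if self.members is not None and len(self.members) != len(self.table):
            raise ValueError("members list must align with the table rows")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["z", "y", "x"]].to_numpy(np.float64)

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def binarize(restored: ImageStack, threshold: float) -> np.ndarray:
    """Foreground mask: restored ratio >= threshold (inclusive)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return restored.data >= threshold


def label_components(
    binary: np.ndarray, connectivity: int = 26
) -> tuple[np.ndarray, int]:
    """Label maximal connected foreground components (background = 0)."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labeled, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    return labeled, int(n)


def filter_objects(objects: ObjectTable, min_volume: int, min_peak: float) -> ObjectTable:
    """Keep objects with volume >= min_volume and peak >= min_peak."""
    keep = (
        (objects.table["volume_voxels"] >= min_volume)
        & (objects.table["peak_ratio"] >= min_peak)
    ).to_numpy()
    table = objects.table.loc[keep].reset_index(drop=True)
    members = (
        [m for m, k in zip(objects.members, keep) if k]
        if objects.members is not None
        else None
    )
    return ObjectTable(
        table=table,
        voxel_size_um=objects.voxel_size_um,
        sample_id=objects.sample_id,
        members=members,
    )


def detect(
    restored: ImageStack,
    params: DetectionParams | None = None,
    sample_id: str = "sample",
    keep_members: bool = True,
) -> ObjectTable:
    """Binarize, label, measure and filter: the full detection step.

    Centroids are the unweighted mean of member voxel coordinates; the
    peak is the maximum restored ratio within the component.  The whole
    step is deterministic.
    """
    params = params or DetectionParams()
    binary = binarize(restored, params.intensity_threshold)
    labeled, n = label_components(binary, params.connectivity)

    if n == 0:
        table = pd.DataFrame(columns=list(ObjectTable.COLUMNS))
        return ObjectTable(
            table=table, voxel_size_um=restored.voxel_size_um,
            sample_id=sample_id, members=[] if keep_members else None,
        )

    ids = np.arange(1, n + 1)
    volumes = ndimage.sum_labels(binary, labeled, ids).astype(np.int64)
    peaks = ndimage.maximum(restored.data, labeled, ids)
    centroids = np.asarray(ndimage.center_of_mass(binary, labeled, ids))

    table = pd.DataFrame(
        {
            "sample_id": sample_id,
            "object_id": ids,
            "z": centroids[:, 0],
            "y": centroids[:, 1],
            "x": centroids[:, 2],
            "volume_voxels": volumes,
            "peak_ratio": peaks,
        }
    )
    members: list[np.ndarray] | None = None
    if keep_members:
        coords = np.argwhere(labeled > 0)
        lab = labeled[coords[:, 0], coords[:, 1], coords[:, 2]]
        order = np.argsort(lab, kind="stable")
        coords, lab = coords[order], lab[order]
        bounds = np.searchsorted(lab, np.arange(1, n + 2))
        members = [coords[bounds[i] : bounds[i + 1]] for i in range(n)]

    raw = ObjectTable(
        table=table, voxel_size_um=restored.voxel_size_um,
        sample_id=sample_id, members=members,
    )
    return filter_objects(raw, params.min_volume, params.min_peak)
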