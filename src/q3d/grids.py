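"""Core gridded containers shared across the pipeline.

An :class:`ImageStack` is a raw (or restored) 3D single-channel volume on
the native acquisition grid, with an anisotropic physical voxel size in
micrometres.  A :class:`VoxelMap` is a scalar field on the isotropic
atlas grid (counts, sizes, volumes, or statistics).  Axis order is
``(z, y, x)`` everywhere, matching how volumetric TIFF stacks are read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Atlas grid spacing in micrometres per voxel side (isotropic).
ATLAS_RESOLUTION_UM = 25.0

#: Quantities a VoxelMap may carry, with their units.
MAP_UNITS = {
    "count": "objects",
    "size_sum": "um^3",
    "mean_size": "um^3",
    "volume_mm3": "mm^3",
    "t": "dimensionless",
    "p": "probability",
    "tfce": "dimensionless",
    "intensity": "a.u.",
}


@dataclass
class ImageStack:
    """3D intensity volume with physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.
    voxel_size_um
        Physical voxel edge lengths ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel size must be three positive lengths, got {vs}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx


@dataclass
class VoxelMap:
    """Scalar field on the atlas grid.

    ``quantity`` names what each voxel holds (see :data:`MAP_UNITS`);
    ``resolution_um`` is the isotropic grid spacing.
    """

    data: np.ndarray
    quantity: str = "count"
    resolution_um: float = ATLAS_RESOLUTION_UM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D map, got shape {self.data.shape}")
        if self.quantity not in MAP_UNITS:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; known: {sorted(MAP_UNITS)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def units(self) -> str:
        return MAP_UNITS[self.quantity]

    def like(self, data: np.ndarray, quantity: str | None = None) -> "VoxelMap":
        """A new map on the same grid holding ``data``."""
        return VoxelMap(
            data=data,
            quantity=self.quantity if quantity is None else quantity,
            resolution_um=self.resolution_um,
            meta=dict(self.meta),
        )
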