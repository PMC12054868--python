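"""Volume and table readers/writers.

Volumes travel as multi-page TIFF or NIfTI.  Physical voxel size is
never guessed: it is read from metadata where the format carries it
(NIfTI header zooms, ImageJ-style TIFF tags) and must otherwise be
supplied explicitly — a missing voxel size is a hard error.

NIfTI convention used here: spatial units are micrometres (xyzt_units
set to micron), header zooms are the voxel edge lengths, and the array
axis order ``(z, y, x)`` is preserved as stored.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

from .atlas import LabelAtlas
from .grids import ImageStack, VoxelMap

import pandas as pd


class VoxelSizeError(ValueError):
    """Raised when a volume's physical voxel size cannot be determined."""


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def _tiff_voxel_size(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Voxel size (z, y, x) in µm from ImageJ-style TIFF metadata."""
    meta = tif.imagej_metadata
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    if meta is None or "spacing" not in meta:
        return None
    unit = (meta.get("unit") or "").lower()
    if unit not in ("micron", "um", "µm"):
        return None
    dx = xres[1] / xres[0]
    dy = yres[1] / yres[0]
    dz = float(meta["spacing"])
    return (dz, dy, dx)


def read_volume(path, voxel_size_um=None) -> ImageStack:
    """Read a TIFF stack or NIfTI volume into an :class:`ImageStack`.

    ``voxel_size_um`` overrides (or supplies, when metadata lacks it)
    the physical voxel size as ``(dz, dy, dx)``.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        if voxel_size_um is None:
            zooms = img.header.get_zooms()[:3]
            if any(z <= 0 for z in zooms):
                raise VoxelSizeError(f"{path}: NIfTI header has no usable zooms")
            voxel_size_um = tuple(float(z) for z in zooms)
        return ImageStack(data=data, voxel_size_um=voxel_size_um)
    if suffixes.endswith((".tif", ".tiff")):
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            if voxel_size_um is None:
                voxel_size_um = _tiff_voxel_size(tif)
        if voxel_size_um is None:
            raise VoxelSizeError(
                f"{path}: TIFF carries no voxel-size metadata; pass voxel_size_um "
                "explicitly (physical units are never guessed)"
            )
        if data.ndim == 2:
            data = data[None]
        return ImageStack(data=data, voxel_size_um=voxel_size_um)
    raise ValueError(f"{path}: unsupported volume format (use .tif/.tiff/.nii/.nii.gz)")


def write_volume(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as TIFF (ImageJ metadata) or NIfTI."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    dz, dy, dx = stack.voxel_size_um
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(np.asarray(stack.data), affine=np.diag([dx, dy, dz, 1.0]))
        img.header.set_zooms((dz, dy, dx))
        img.header.set_xyzt_units(xyz="micron")
        nib.save(img, str(path))
        return
    if suffixes.endswith((".tif", ".tiff")):
        data = np.asarray(stack.data)
        if data.dtype == np.float64:
            # ImageJ-style TIFF carries 32-bit floats at most; the
            # round-trip contract covers integer and float32 data
            data = data.astype(np.float32)
        tifffile.imwrite(
            str(path),
            data,
            imagej=True,
            resolution=(1.0 / dx, 1.0 / dy),
            metadata={"spacing": dz, "unit": "micron", "axes": "ZYX"},
        )
        return
    raise ValueError(f"{path}: unsupported volume format (use .tif/.tiff/.nii/.nii.gz)")


def write_map(vmap: VoxelMap, path) -> None:
    """Write a :class:`VoxelMap` as NIfTI with quantity/units in the
    header description."""
    path = Path(path)
    r = vmap.resolution_um
    img = nib.Nifti1Image(np.asarray(vmap.data, dtype=np.float64), affine=np.diag([r, r, r, 1.0]))
    img.header.set_zooms((r, r, r))
    img.header.set_xyzt_units(xyz="micron")
    img.header["descrip"] = f"{vmap.quantity} [{vmap.units}]".encode()[:79]
    nib.save(img, str(path))


def read_map(path, quantity: str = "count") -> VoxelMap:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if len(set(np.round(zooms, 9))) != 1:
        raise VoxelSizeError(f"{path}: atlas-space maps must be isotropic, got {zooms}")
    return VoxelMap(
        data=np.asarray(img.dataobj, dtype=np.float64),
        quantity=quantity,
        resolution_um=float(zooms[0]),
    )


# ---------------------------------------------------------------------------
# Atlases and tables
# ---------------------------------------------------------------------------

def write_atlas(atlas: LabelAtlas, volume_path, table_path) -> None:
    r = atlas.resolution_um
    img = nib.Nifti1Image(
        np.asarray(atlas.labels, dtype=np.int32), affine=np.diag([r, r, r, 1.0])
    )
    img.header.set_zooms((r, r, r))
    img.header.set_xyzt_units(xyz="micron")
    nib.save(img, str(volume_path))
    atlas.regions.to_csv(table_path, index=False)


def read_atlas(volume_path, table_path) -> LabelAtlas:
    img = nib.load(str(volume_path))
    zooms = img.header.get_zooms()[:3]
    labels = np.asarray(img.dataobj).astype(np.int32)
    regions = pd.read_csv(table_path)
    return LabelAtlas(labels=labels, regions=regions, resolution_um=float(zooms[0]))


# ---------------------------------------------------------------------------
# YAML config snapshots
# ---------------------------------------------------------------------------

def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
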