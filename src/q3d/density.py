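"""Spherical-ROI smoothing of atlas-space maps into heatmaps.

A local density heatmap places a spherical region of interest (default
diameter 15 atlas voxels = 375 µm at 25 µm resolution) at every atlas
voxel and sums the map values inside it.  For mean object size, the
size-sum and count maps are smoothed with the same kernel and divided;
voxels whose smoothed count is zero are undefined (NaN) rather than
zero, so they can be excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .grids import VoxelMap

DEFAULT_DIAMETER = 15


@dataclass(frozen=True)
class SphereKernel:
    """Discrete spherical ROI on the atlas grid.

    Offsets are all integer triples with squared Euclidean distance from
    the centre at most ``(diameter / 2)**2``, compared in exact integer
    arithmetic (``4 * |d|^2 <= diameter^2``) to keep the boundary
    decision float-free.  Weights default to uniform 1 (a plain sum over
    the ROI); ``radial`` weights fall off linearly with distance.
    """

    diameter: int = DEFAULT_DIAMETER
    weighting: str = "uniform"

    def __post_init__(self) -> None:
        if self.diameter < 1 or self.diameter % 2 == 0:
            raise ValueError("diameter must be an odd positive integer "
                             "(an even diameter has no centre voxel)")
        if self.weighting not in ("uniform", "radial"):
            raise ValueError("weighting must be 'uniform' or 'radial'")

    @property
    def radius(self) -> int:
        return self.diameter // 2

    def physical_diameter_um(self, resolution_um: float) -> float:
        """Physical ROI diameter: voxel count times voxel side."""
        return self.diameter * resolution_um

    def offsets(self) -> np.ndarray:
        return sphere_offsets(self.diameter)

    def footprint(self) -> np.ndarray:
        """Dense (d, d, d) weight array of the kernel."""
        r = self.radius
        ax = np.arange(-r, r + 1)
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        d2 = zz**2 + yy**2 + xx**2
        inside = 4 * d2 <= self.diameter**2
        if self.weighting == "uniform":
            w = inside.astype(np.float64)
        else:
            w = np.where(inside, 1.0 - np.sqrt(d2) / (self.diameter / 2.0), 0.0)
        return w

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.footprint() > 0))


def sphere_offsets(diameter: int) -> np.ndarray:
    """Integer offsets of a spherical ROI, centre included.

    All ``(dz, dy, dx)`` with ``4 * (dz² + dy² + dx²) <= diameter²``.
    """
    if diameter < 1 or diameter % 2 == 0:
        raise ValueError("diameter must be an odd positive integer")
    r = diameter // 2
    ax = np.arange(-r, r + 1)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    d2 = zz**2 + yy**2 + xx**2
    inside = 4 * d2 <= diameter**2
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)


def smooth_map(
    vmap: VoxelMap,
    kernel: SphereKernel | None = None,
    method: str = "direct",
) -> VoxelMap:
    """ROI sum (or weighted sum) of the map at every voxel.

    ``out(v) = sum over offsets d with v+d inside of w(d) * map(v+d)``;
    the sphere is truncated at the volume boundary (no renormalization).
    ``method='direct'`` evaluates the literal sum; ``method='fft'`` is a
    numerically equivalent FFT convolution (faster on large maps, with
    float round-off at the 1e-12 level).
    """
    kernel = kernel or SphereKernel()
    w = kernel.footprint()
    data = vmap.data.astype(np.float64, copy=False)
    if method == "direct":
        out = ndimage.correlate(data, w, mode="constant", cval=0.0)
    elif method == "fft":
        out = signal.fftconvolve(data, w[::-1, ::-1, ::-1], mode="same")
    else:
        raise ValueError("method must be 'direct' or 'fft'")
    res = vmap.like(out)
    res.meta["roi_diameter"] = kernel.diameter
    res.meta["roi_weighting"] = kernel.weighting
    return res


def mean_size_heatmap(
    size_sum: VoxelMap,
    count: VoxelMap,
    kernel: SphereKernel | None = None,
    method: str = "direct",
) -> VoxelMap:
    """Per-voxel mean object size over the ROI: smoothed size-sum over
    smoothed count; NaN where the smoothed count is zero."""
    if size_sum.shape != count.shape:
        raise ValueError("size_sum and count maps must share a grid")
    s = smooth_map(size_sum, kernel, method=method)
    c = smooth_map(count, kernel, method=method)
    out = np.full(s.shape, np.nan, dtype=np.float64)
    defined = c.data > 0
    out[defined] = s.data[defined] / c.data[defined]
    res = s.like(out, quantity="mean_size")
    res.meta["n_undefined"] = int((~defined).sum())
    return res
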