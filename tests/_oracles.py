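"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a route structurally different from
the library's: breadth-first flood fill instead of union-find / ndimage
labeling, per-threshold cluster relabeling instead of the incremental
TFCE sweep, explicit voxel loops instead of vectorized accumulation.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage


def flood_fill_label(binary: np.ndarray, connectivity: int = 26):
    """BFS connected-component labeling of a 3D boolean volume."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    nz, ny, nx = binary.shape
    labels = np.zeros(binary.shape, dtype=np.int64)
    next_label = 0
    for z0, y0, x0 in np.argwhere(binary):
        if labels[z0, y0, x0]:
            continue
        next_label += 1
        labels[z0, y0, x0] = next_label
        queue = deque([(z0, y0, x0)])
        while queue:
            z, y, x = queue.popleft()
            for dz, dy, dx in offsets:
                zz, yy, xx = z + dz, y + dy, x + dx
                if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx:
                    if binary[zz, yy, xx] and not labels[zz, yy, xx]:
                        labels[zz, yy, xx] = next_label
                        queue.append((zz, yy, xx))
    return labels, next_label


def partitions_equal(lab_a: np.ndarray, lab_b: np.ndarray) -> bool:
    """Whether two labelings induce the same partition of the foreground."""
    if not np.array_equal(lab_a > 0, lab_b > 0):
        return False
    fg = lab_a > 0
    pairs = set(zip(lab_a[fg].tolist(), lab_b[fg].tolist()))
    # a bijection between label sets: each label appears in exactly one pair
    return (
        len(pairs)
        == len({a for a, _ in pairs})
        == len({b for _, b in pairs})
    )


def brute_force_tfce(
    stat: np.ndarray, E: float, H: float, n_steps: int, connectivity: int = 26
) -> np.ndarray:
    """TFCE by independent relabeling at every threshold of the grid
    ``h_k = k * max|stat| / n_steps``."""
    stat = np.nan_to_num(np.asarray(stat, dtype=np.float64))
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    out = np.zeros_like(stat)
    hmax = float(np.abs(stat).max())
    if hmax <= 0:
        return out
    dh = hmax / n_steps
    for sign in (1.0, -1.0):
        side = sign * stat
        for k in range(1, n_steps + 1):
            h = k * dh
            sup = side >= h
            if not sup.any():
                continue
            lab, _ = ndimage.label(sup, structure=struct)
            sizes = np.bincount(lab.ravel()).astype(np.float64)
            out[sup] += sign * (sizes[lab[sup]] ** E) * (h**H) * dh
    return out


def loop_colocalization(sign_a: np.ndarray, sign_b: np.ndarray) -> dict:
    """Exhaustive voxel loop counting signed overlaps of two sign maps."""
    counts = {(sa, sb): 0 for sa in (1, -1) for sb in (1, -1)}
    for a, b in zip(sign_a.ravel().tolist(), sign_b.ravel().tolist()):
        if a != 0 and b != 0:
            counts[(a, b)] += 1
    return counts


def enumerate_sphere_offsets(diameter: int) -> set:
    """All integer offsets within diameter/2, by exhaustive cube scan."""
    r = diameter // 2
    out = set()
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if 4 * (dz * dz + dy * dy + dx * dx) <= diameter * diameter:
                    out.add((dz, dy, dx))
    return out


def separable_gaussian_response(shape, point, sigma: float) -> np.ndarray:
    """Response of a unit impulse under reflective-boundary Gaussian
    smoothing, built from explicit 1D truncated kernels."""
    # scipy's default truncation: radius = int(4 * sigma + 0.5)
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    out = np.zeros(shape)
    out[tuple(point)] = 1.0
    for axis in range(3):
        padded = np.concatenate(
            [
                np.flip(out, axis=axis).take(range(out.shape[axis] - radius, out.shape[axis]), axis=axis),
                out,
                np.flip(out, axis=axis).take(range(0, radius), axis=axis),
            ],
            axis=axis,
        )
        out = np.apply_along_axis(
            lambda v: np.convolve(v, k, mode="valid"), axis, padded
        )
    return out
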