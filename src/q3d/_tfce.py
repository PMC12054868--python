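"""Numba kernel for threshold-free cluster enhancement.

TFCE of a nonnegative statistic field is, per voxel,

    TFCE(v) = sum over thresholds h in {dh, 2dh, ..., K dh}
              of e(v, h)^E * h^H * dh   for h <= stat(v),

where ``e(v, h)`` is the voxel count of the connected suprathreshold
cluster containing ``v`` at height ``h``.  Rather than relabeling the
volume at every threshold, the sweep processes thresholds from high to
low with a union-find forest: voxels activate when the threshold drops
below their value, clusters merge incrementally, and each live root
accumulates its cluster's increment.  Per-voxel totals are recovered via
potential offsets recorded at every merge, so the result equals the
per-threshold definition up to floating-point round-off.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _find(parent, off, x):
    """Root of x and the summed potential offset along the path."""
    root = x
    acc = 0.0
    while parent[root] != root:
        acc += off[root]
        root = parent[root]
    # path compression, keeping each node's offset-to-root consistent
    cur = x
    rem = acc
    while parent[cur] != root:
        nxt = parent[cur]
        o = off[cur]
        parent[cur] = root
        off[cur] = rem
        rem -= o
        cur = nxt
    return root, acc


@njit(cache=False)
def _union(parent, off, size, accv, a, b):
    ra, _ = _find(parent, off, a)
    rb, _ = _find(parent, off, b)
    if ra == rb:
        return
    if size[ra] < size[rb]:
        ra, rb = rb, ra
    # members of rb have accumulated accv[rb] so far; preserve that
    parent[rb] = ra
    off[rb] = accv[rb] - accv[ra]
    size[ra] += size[rb]


@njit(cache=False)
def _tfce_sweep(vals, order, nz, ny, nx, dzs, dys, dxs,
                dh, n_steps, E, H, sign, out):
    """Accumulate sign * TFCE of ``vals`` (flat, >= 0) into ``out``."""
    n = vals.size
    parent = np.full(n, -1, np.int64)
    off = np.zeros(n, np.float64)
    accv = np.zeros(n, np.float64)
    size = np.zeros(n, np.int64)
    roots = np.empty(n, np.int64)
    nroots = 0
    ptr = 0
    nyx = ny * nx
    nneigh = dzs.size
    for k in range(n_steps, 0, -1):
        h = k * dh
        while ptr < n:
            v = order[ptr]
            if vals[v] < h:
                break
            ptr += 1
            parent[v] = v
            size[v] = 1
            roots[nroots] = v
            nroots += 1
            z = v // nyx
            rest = v - z * nyx
            y = rest // nx
            x = rest - y * nx
            for d in range(nneigh):
                zz = z + dzs[d]
                if zz < 0 or zz >= nz:
                    continue
                yy = y + dys[d]
                if yy < 0 or yy >= ny:
                    continue
                xx = x + dxs[d]
                if xx < 0 or xx >= nx:
                    continue
                w = zz * nyx + yy * nx + xx
                if parent[w] != -1:
                    _union(parent, off, size, accv, v, w)
        if nroots == 0:
            continue
        hterm = h ** H * dh
        nr = 0
        for i in range(nroots):
            r = roots[i]
            if parent[r] == r:
                accv[r] += size[r] ** E * hterm
                roots[nr] = r
                nr += 1
        nroots = nr
    for v in range(n):
        if parent[v] != -1:
            root, path = _find(parent, off, v)
            out[v] += sign * (accv[root] + path)


def tfce_array(
    stat: np.ndarray,
    E: float,
    H: float,
    n_steps: int,
    neighbor_offsets: np.ndarray,
) -> np.ndarray:
    """Signed TFCE of a 3D statistic map.

    Positive and negative parts are enhanced separately on a shared
    threshold grid ``h_k = k * max|stat| / n_steps`` and recombined with
    their signs.  NaNs (masked voxels) contribute nothing and stay 0.
    """
    stat = np.nan_to_num(np.asarray(stat, dtype=np.float64), copy=True)
    nz, ny, nx = stat.shape
    out = np.zeros(stat.size, dtype=np.float64)
    hmax = float(np.abs(stat).max()) if stat.size else 0.0
    if hmax <= 0 or n_steps < 1:
        return out.reshape(stat.shape)
    dh = hmax / n_steps
    dzs = np.ascontiguousarray(neighbor_offsets[:, 0])
    dys = np.ascontiguousarray(neighbor_offsets[:, 1])
    dxs = np.ascontiguousarray(neighbor_offsets[:, 2])
    for sign in (1.0, -1.0):
        vals = np.where(sign * stat > 0, sign * stat, 0.0).ravel()
        order = np.argsort(-vals, kind="stable").astype(np.int64)
        _tfce_sweep(vals, order, nz, ny, nx, dzs, dys, dxs,
                    dh, n_steps, float(E), float(H), sign, out)
    return out.reshape(stat.shape)
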