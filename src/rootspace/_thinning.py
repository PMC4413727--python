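"""Sequential distance-ordered homotopic 3D thinning.

Reduces a binary volume to a 1-voxel-wide curve skeleton by deleting
simple points — voxels whose removal changes neither the number of
foreground 26-components in their neighborhood nor the 6-connectivity of
the adjacent background (Bertrand's two-count characterization) — in
ascending order of the Euclidean distance transform, so outer layers peel
first and the result tracks the medial axis. Deletion is strictly
sequential (every candidate is re-examined against the current image),
which preserves topology exactly: symmetric voxel pairs can never be
removed in the same step. Curve endpoints (voxels with at most one
foreground neighbor) are never deleted, so branch tips survive.

Deterministic: ties in the distance ordering are broken by flat voxel
index.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["thin_volume"]

# flat index of the center of a 3x3x3 block (C order)
_CENTER = 13

# 6-face neighbor flat offsets within a 3x3x3 block, relative coordinates
_FACE_FLAT = np.array([4, 10, 12, 14, 16, 22], dtype=np.int64)


@njit(cache=True)
def _fill_neighborhood(img, x, y, z, nb):
    n = 0
    k = 0
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            for dz in range(-1, 2):
                v = img[x + dx, y + dy, z + dz]
                nb[k] = v
                if v and k != 13:
                    n += 1
                k += 1
    return n


@njit(cache=True)
def _one_fg_component_26(nb):
    """True iff the foreground of the punctured 3x3x3 block is one
    26-connected component."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    ncomp = 0
    for start in range(27):
        if start == _CENTER or nb[start] == 0 or visited[start]:
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        top = 0
        stack[top] = start
        top += 1
        visited[start] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cx = cur // 9
            cy = (cur % 9) // 3
            cz = cur % 3
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    for dz in range(-1, 2):
                        nx = cx + dx
                        ny = cy + dy
                        nz = cz + dz
                        if 0 <= nx < 3 and 0 <= ny < 3 and 0 <= nz < 3:
                            ni = nx * 9 + ny * 3 + nz
                            if ni != _CENTER and nb[ni] and not visited[ni]:
                                visited[ni] = 1
                                stack[top] = ni
                                top += 1
    return ncomp == 1


@njit(cache=True)
def _in_n18(flat):
    """Cell of the 3x3x3 block belongs to the 18-neighborhood (face or
    edge neighbor of the center)."""
    x = flat // 9
    y = (flat % 9) // 3
    z = flat % 3
    d = abs(x - 1) + abs(y - 1) + abs(z - 1)
    return 1 <= d <= 2


@njit(cache=True)
def _one_bg_component_6(nb):
    """True iff the background cells of the 18-neighborhood that are
    6-reachable from the center form one 6-connected component."""
    visited = np.zeros(27, np.uint8)
    stack = np.empty(27, np.int64)
    ncomp = 0
    for s in range(6):
        start = _FACE_FLAT[s]
        if nb[start] != 0 or visited[start]:
            continue
        ncomp += 1
        if ncomp > 1:
            return False
        top = 0
        stack[top] = start
        top += 1
        visited[start] = 1
        while top > 0:
            top -= 1
            cur = stack[top]
            cx = cur // 9
            cy = (cur % 9) // 3
            cz = cur % 3
            # 6-connected moves, restricted to the 18-neighborhood
            for axis in range(3):
                for step in (-1, 1):
                    nx, ny, nz = cx, cy, cz
                    if axis == 0:
                        nx += step
                    elif axis == 1:
                        ny += step
                    else:
                        nz += step
                    if 0 <= nx < 3 and 0 <= ny < 3 and 0 <= nz < 3:
                        ni = nx * 9 + ny * 3 + nz
                        if (
                            ni != _CENTER
                            and _in_n18(ni)
                            and nb[ni] == 0
                            and not visited[ni]
                        ):
                            visited[ni] = 1
                            stack[top] = ni
                            top += 1
    return ncomp == 1


@njit(cache=True)
def _thin_inplace(img, order_x, order_y, order_z):
    """Sequentially delete simple non-endpoint voxels until stable."""
    nb = np.empty(27, np.uint8)
    changed = True
    while changed:
        changed = False
        for t in range(order_x.shape[0]):
            x = order_x[t]
            y = order_y[t]
            z = order_z[t]
            if img[x, y, z] == 0:
                continue
            n_fg = _fill_neighborhood(img, x, y, z, nb)
            if n_fg <= 1:
                continue  # endpoint or isolated: keep
            if _one_fg_component_26(nb) and _one_bg_component_6(nb):
                img[x, y, z] = 0
                changed = True


def thin_volume(occupancy: np.ndarray) -> np.ndarray:
    """Curve skeleton of a binary volume; same shape, boolean.

    Each 26-connected component thins to a 1-voxel-wide, topology-
    equivalent curve network; isolated voxels and single-voxel components
    survive unchanged.
    """
    occ = np.ascontiguousarray(occupancy.astype(np.uint8))
    if not occ.any():
        return np.zeros_like(occ, dtype=bool)
    img = np.pad(occ, 1)
    dist = ndimage.distance_transform_edt(img)
    xs, ys, zs = np.nonzero(img)
    flat = (xs * img.shape[1] + ys) * img.shape[2] + zs
    order = np.lexsort((flat, dist[xs, ys, zs]))
    _thin_inplace(img, xs[order], ys[order], zs[order])
    return img[1:-1, 1:-1, 1:-1].astype(bool)
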