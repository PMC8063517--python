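"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and the libraries
behind them): set-based cell counting for the Euler characteristic, dense
direct convolution, BFS flood fill, per-box scans, and a literal
fixed-point iteration for the intermeans threshold.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import product

import numpy as np


def chi_cells(voxels: np.ndarray):
    """Distinct vertices/edges/faces/cubes of the union of closed unit cubes."""
    verts, edges, faces, cubes = set(), set(), set(), set()
    for z, y, x in map(tuple, np.argwhere(voxels)):
        cubes.add((z, y, x))
        for dz, dy, dx in product((0, 1), repeat=3):
            verts.add((z + dz, y + dy, x + dx))
        for axis in range(3):
            for da, db in product((0, 1), repeat=2):
                corner = [z, y, x]
                other = [a for a in range(3) if a != axis]
                corner[other[0]] += da
                corner[other[1]] += db
                edges.add((tuple(corner), axis))
        for axis in range(3):  # face normal
            for d in (0, 1):
                corner = [z, y, x]
                corner[axis] += d
                faces.add((tuple(corner), axis))
    return verts, edges, faces, cubes


def chi_oracle(voxels: np.ndarray) -> int:
    """chi = V - E + F - C by exhaustive distinct-cell enumeration."""
    verts, edges, faces, cubes = chi_cells(voxels)
    return len(verts) - len(edges) + len(faces) - len(cubes)


def chi_corrected_oracle(voxels: np.ndarray) -> Fraction:
    """Tiling-weighted chi: each cell weighted 1/2 per bounding-box plane
    that contains it."""
    nz, ny, nx = voxels.shape
    verts, edges, faces, cubes = chi_cells(voxels)

    def vertex_weight(v):
        k = sum(1 for c, n in zip(v, (nz, ny, nx)) if c in (0, n))
        return Fraction(1, 2**k)

    def edge_weight(e):
        corner, axis = e
        k = sum(
            1
            for a, (c, n) in enumerate(zip(corner, (nz, ny, nx)))
            if a != axis and c in (0, n)
        )
        return Fraction(1, 2**k)

    def face_weight(f):
        corner, axis = f
        n = (nz, ny, nx)[axis]
        return Fraction(1, 2) if corner[axis] in (0, n) else Fraction(1)

    total = sum(vertex_weight(v) for v in verts)
    total -= sum(edge_weight(e) for e in edges)
    total += sum(face_weight(f) for f in faces)
    total -= len(cubes)
    return Fraction(total)


def dense_gaussian_3d(volume: np.ndarray, sigma: float) -> np.ndarray:
    """Triple application of the 1D truncated kernel by direct convolution
    with symmetric (reflective) borders."""
    radius = int(np.ceil(3 * sigma))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2 * sigma**2))
    kernel /= kernel.sum()
    out = volume.astype(float)
    for axis in range(3):
        padded = np.pad(out, [(radius, radius) if a == axis else (0, 0) for a in range(3)], mode="symmetric")
        new = np.zeros_like(out)
        for k, w in enumerate(kernel):
            sl = [slice(None)] * 3
            sl[axis] = slice(k, k + out.shape[axis])
            new += w * padded[tuple(sl)]
        out = new
    return out


def intermeans_fixed_point(hist: np.ndarray) -> int:
    """Smallest integer split s with (mean_below + mean_above)/2 in [s, s+1);
    returns the rounded fixed-point level."""
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(len(hist), dtype=float)
    populated = np.flatnonzero(hist)
    lo, hi = int(populated[0]), int(populated[-1])
    for s in range(lo, hi):
        below = hist[: s + 1]
        above = hist[s + 1 :]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mb = (bins[: s + 1] * below).sum() / below.sum()
        ma = (bins[s + 1 :] * above).sum() / above.sum()
        t = (mb + ma) / 2.0
        if s <= t < s + 1:
            return int(round(t))
    raise AssertionError("no fixed point found")


def flood_fill_components(voxels: np.ndarray, connectivity: int) -> int:
    """Number of connected components by BFS."""
    if connectivity == 6:
        neigh = [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1]
    else:
        neigh = [o for o in product((-1, 0, 1), repeat=3) if any(o)]
    seen = np.zeros(voxels.shape, dtype=bool)
    count = 0
    for start in map(tuple, np.argwhere(voxels)):
        if seen[start]:
            continue
        count += 1
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            for o in neigh:
                q = tuple(a + b for a, b in zip(p, o))
                if all(0 <= c < n for c, n in zip(q, voxels.shape)) and voxels[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
    return count


def box_count_scan(voxels: np.ndarray, size: int) -> int:
    """Occupied boxes by a literal per-box triple loop."""
    nz, ny, nx = voxels.shape
    count = 0
    for z0 in range(0, nz, size):
        for y0 in range(0, ny, size):
            for x0 in range(0, nx, size):
                if voxels[z0 : z0 + size, y0 : y0 + size, x0 : x0 + size].any():
                    count += 1
    return count
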