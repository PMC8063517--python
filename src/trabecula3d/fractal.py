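"""Box-counting fractal dimension of a binary 3D structure.

The stack is tiled with cubic boxes of decreasing edge length; the number
of boxes containing any foreground voxel grows as ``size**-D`` for a
structure of fractal dimension D, recovered as the negative slope of the
least-squares line through ``log(count)`` vs ``log(size)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import BinaryMask

__all__ = ["BoxCountSeries", "default_box_sizes", "box_counts", "box_counts_jitter", "fractal_dimension"]


@dataclass
class BoxCountSeries:
    """Box sizes (voxel edge lengths, decreasing) and occupied-box counts.

    Counts may be fractional when produced by jitter averaging.
    """

    sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.sizes) != len(self.counts):
            raise ValueError("sizes and counts must have equal length")
        order = np.argsort(-self.sizes, kind="stable")
        self.sizes = self.sizes[order]
        self.counts = self.counts[order]
        if (np.diff(self.counts) < 0).any():
            raise ValueError("counts must be non-decreasing as box size decreases")


def default_box_sizes(shape) -> list[int]:
    """Powers of 2 from ``min(shape) // 4`` down to 1."""
    top = max(min(shape) // 4, 1)
    sizes = []
    s = 1
    while s <= top:
        sizes.append(s)
        s *= 2
    return sizes[::-1]


def _count_at(voxels: np.ndarray, size: int, origin=(0, 0, 0)) -> int:
    """Occupied boxes of edge ``size`` tiling from ``origin`` (which may be
    negative, extending the tiling before the stack)."""
    pad_lo = [int(-o) % size for o in origin]
    padded = np.pad(voxels, [(p, 0) for p in pad_lo])
    pad_hi = [(-s) % size for s in padded.shape]
    padded = np.pad(padded, [(0, p) for p in pad_hi])
    z, y, x = (n // size for n in padded.shape)
    blocks = padded.reshape(z, size, y, size, x, size)
    return int(blocks.any(axis=(1, 3, 5)).sum())


def box_counts(mask: BinaryMask, sizes) -> BoxCountSeries:
    """Occupied-box counts with the tiling anchored at the stack origin."""
    sizes = np.asarray(sorted(set(int(s) for s in np.atleast_1d(sizes)), reverse=True))
    if (sizes < 1).any():
        raise ValueError("box sizes must be >= 1")
    if mask.foreground_count == 0:
        raise ValueError("box counting an empty mask is undefined")
    counts = [_count_at(mask.voxels, int(s)) for s in sizes]
    return BoxCountSeries(sizes, np.asarray(counts))


def box_counts_jitter(mask: BinaryMask, sizes) -> BoxCountSeries:
    """Counts averaged over 8 tiling origins (shifted by half a box per
    axis), reducing the bias of an arbitrary grid placement."""
    sizes = np.asarray(sorted(set(int(s) for s in np.atleast_1d(sizes)), reverse=True))
    if (sizes < 1).any():
        raise ValueError("box sizes must be >= 1")
    if mask.foreground_count == 0:
        raise ValueError("box counting an empty mask is undefined")
    counts = []
    for s in sizes:
        shifts = (0, -(int(s) // 2)) if s > 1 else (0,)
        vals = [
            _count_at(mask.voxels, int(s), origin)
            for origin in product(shifts, repeat=3)
        ]
        counts.append(float(np.mean(vals)))
    return BoxCountSeries(sizes, np.asarray(counts))


def fractal_dimension(series: BoxCountSeries) -> float:
    """Negative least-squares slope of log(count) against log(size)."""
    if len(series.sizes) < 3:
        raise ValueError("need at least 3 box sizes for a meaningful fit")
    slope = np.polyfit(np.log(series.sizes.astype(float)), np.log(series.counts), 1)[0]
    return float(-slope)
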