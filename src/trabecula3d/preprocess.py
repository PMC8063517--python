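"""Stack preprocessing: 3D Gaussian smoothing, automatic thresholding,
binarisation, connected components and Purify.

The threshold routine is the classic iterative-intermeans ("isodata
variant") selector that ImageJ ships as its *Default* method, computed on
the full-stack histogram.  *Purify* prepares a mask for connectivity
analysis: it keeps the largest 26-connected bone particle and fills every
enclosed marrow cavity so that exactly one particle on one background
remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Image3D, _BIT_DEPTHS

__all__ = [
    "ThresholdBounds",
    "LabelField",
    "gaussian_blur_3d",
    "default_threshold",
    "to_mask",
    "connected_components",
    "purify",
]


@dataclass(frozen=True)
class ThresholdBounds:
    """Inclusive intensity window; voxels inside it become foreground."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")


@dataclass
class LabelField:
    """Connected-component labelling: 0 = background, 1..n_labels ordered by
    descending voxel count (label 1 is the largest particle)."""

    voxels: np.ndarray
    n_labels: int
    connectivity: int

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    def count(self, label: int) -> int:
        return int((self.voxels == label).sum())


def gaussian_blur_3d(image: Image3D, sigma) -> Image3D:
    """Separable 3D Gaussian smoothing with a kernel truncated at radius
    ``ceil(3*sigma)`` and reflective borders.

    ``sigma`` is per-axis ``(z, y, x)`` in voxels (a scalar applies to all
    axes).  Integer-depth images are filtered in float and rounded back.
    """
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (3,))
    if (sigma <= 0).any():
        raise ValueError(f"sigma must be positive on every axis, got {tuple(sigma)}")
    radius = tuple(int(np.ceil(3 * s)) for s in sigma)
    blurred = ndimage.gaussian_filter(
        image.voxels.astype(np.float64), sigma=tuple(sigma), mode="reflect", radius=radius
    )
    if image.bit_depth == "float":
        out = blurred.astype(np.float32)
    else:
        info = np.iinfo(_BIT_DEPTHS[image.bit_depth])
        out = np.clip(np.rint(blurred), info.min, info.max).astype(info.dtype)
    return Image3D(out, image.bit_depth, image.calibration)


def default_threshold(histogram: np.ndarray) -> ThresholdBounds:
    """ImageJ "Default" (iterative intermeans) threshold, dark background.

    Iterates ``t <- (mean below t + mean above t) / 2`` to its fixed point on
    the stack histogram.  Returns the first bin *above* the fixed point as
    the lower bound and the last histogram bin as the upper bound, i.e. the
    foreground window of a dark-background image.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or len(hist) < 2:
        raise ValueError("histogram must be a 1D array with at least two bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    populated = np.flatnonzero(hist)
    if len(populated) < 2:
        raise ValueError("degenerate histogram: fewer than two populated bins")
    lo, hi = int(populated[0]), int(populated[-1])
    bins = np.arange(len(hist), dtype=np.float64)
    moving = lo
    while True:
        below = slice(lo, moving + 1)
        above = slice(moving + 1, hi + 1)
        mean_below = (bins[below] * hist[below]).sum() / hist[below].sum()
        mean_above = (bins[above] * hist[above]).sum() / hist[above].sum()
        result = (mean_below + mean_above) / 2.0
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    level = int(round(result))
    return ThresholdBounds(float(level + 1), float(len(hist) - 1))


def to_mask(image: Image3D, bounds: ThresholdBounds) -> BinaryMask:
    """Binarise: foreground iff ``lower <= value <= upper``."""
    if bounds.upper > image.max_representable:
        raise ValueError(
            f"bounds {bounds} exceed the representable range of a {image.bit_depth}-bit image"
        )
    vox = image.voxels
    return BinaryMask((vox >= bounds.lower) & (vox <= bounds.upper), image.calibration)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: BinaryMask, connectivity: int = 26) -> LabelField:
    """Label foreground particles; labels sorted by descending voxel count.

    Ties in size are broken by the lowest raster index of a component's
    first voxel, so the labelling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6 or 26")
    raw, n = ndimage.label(mask.voxels, structure=_STRUCTURES[connectivity])
    if n == 0:
        return LabelField(raw, 0, connectivity)
    counts = np.bincount(raw.ravel())[1:]
    # scipy assigns raw labels in raster order of first encounter, so a
    # stable sort on count alone realises the first-voxel tie-break
    order = np.argsort(-counts, kind="stable") + 1
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order] = np.arange(1, n + 1)
    return LabelField(remap[raw], n, connectivity)


def purify(mask: BinaryMask) -> BinaryMask:
    """Retain the largest 26-connected particle and fill enclosed cavities.

    The output has exactly one foreground component (26-connectivity) and
    one background component (6-connectivity): all marrow cavities except
    the largest background region — the one reaching the stack boundary in
    any non-degenerate specimen — are filled as bone.
    """
    if mask.foreground_count == 0:
        raise ValueError("cannot purify an empty mask")
    fg = connected_components(mask, 26)
    kept = fg.voxels == 1
    bg = connected_components(BinaryMask(~kept, mask.calibration), 6)
    if bg.n_labels > 1:
        kept = kept | (bg.voxels > 1)  # fill every cavity but the main background
    return BinaryMask(kept, mask.calibration)
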