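"""Model-independent local thickness by the maximal-inscribed-sphere method.

Every foreground voxel is assigned the diameter of the largest sphere that
contains the voxel and fits inside the structure.  The computation follows
the classic three stages: exact Euclidean distance transform (squared
integer distances internally), reduction to the *distance ridge* (centres of
maximal spheres not contained in any other sphere), and sphere painting
(each voxel takes the largest diameter over the ridge spheres covering it).

Applied to the bone phase the map summarises as trabecular thickness
(Tb.Th); applied to the inverted mask it yields trabecular separation
(Tb.Sp).  Background voxels are NaN so they drop out of statistics.

The reported diameter is ``(2*d - 1) * spacing`` for a centre whose nearest
background voxel centre lies at ``d`` voxels: the half-voxel between a
background voxel's centre and the phase boundary on either side is excluded,
so a slab of n voxels measures n voxel-widths thick.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Calibration

__all__ = [
    "ThicknessMap",
    "ThicknessStats",
    "distance_ridge",
    "local_thickness",
    "spacing_map",
    "thickness_stats",
]


@dataclass
class ThicknessMap:
    """Per-voxel local diameter (calibrated units); background is NaN."""

    map: np.ndarray
    calibration: Calibration
    phase: str = "foreground"

    def __post_init__(self) -> None:
        finite = self.map[np.isfinite(self.map)]
        if finite.size and finite.min() <= 0:
            raise ValueError("finite thickness values must be positive")


@dataclass(frozen=True)
class ThicknessStats:
    mean: float
    sd: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0 or self.max < self.mean * (1 - 1e-12):
            raise ValueError(f"inconsistent thickness statistics {self}")


def _squared_edt(voxels: np.ndarray) -> np.ndarray:
    """Exact squared Euclidean distance (in voxels) to the nearest background
    voxel centre, as integers; 0 on background."""
    edt = ndimage.distance_transform_edt(voxels)
    return np.rint(edt * edt).astype(np.int64)


def distance_ridge(mask: BinaryMask) -> np.ndarray:
    """Boolean grid of distance-ridge voxels (centres of maximal spheres).

    A foreground voxel is off the ridge when a 26-neighbour's sphere wholly
    contains its own, i.e. when ``r_q >= r_p + |q - p|`` for some neighbour
    q.  Sphere painting over this (super)set of maximal centres reproduces
    painting over all foreground spheres exactly.
    """
    if mask.foreground_count == 0:
        raise ValueError("distance ridge of an empty mask is undefined")
    d2 = _squared_edt(mask.voxels)
    r = np.sqrt(d2.astype(np.float64))
    covered = np.zeros(mask.shape, dtype=bool)
    for off in product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        dist = float(np.linalg.norm(off))
        shifted = np.full(mask.shape, -np.inf)
        src = tuple(slice(max(o, 0), n + min(o, 0)) for o, n in zip(off, mask.shape))
        dst = tuple(slice(max(-o, 0), n + min(-o, 0)) for o, n in zip(off, mask.shape))
        shifted[dst] = r[src]
        covered |= shifted >= r + dist - 1e-9
    return mask.voxels & ~covered


def _ball_template(r2: int) -> tuple[int, np.ndarray]:
    """Radius bound R and boolean ball of voxels with squared distance < r2."""
    r = float(np.sqrt(r2))
    R = int(np.ceil(r)) - 1
    ax = np.arange(-R, R + 1)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return R, d2 < r2


def local_thickness(mask: BinaryMask, mask_artefacts: bool = True) -> ThicknessMap:
    """Local thickness map of the foreground phase.

    Sphere painting writes a sphere's diameter into every voxel it covers,
    including background voxels it overhangs near phase boundaries.  With
    ``mask_artefacts`` set (the default) the map is masked to the measured
    phase, removing those overhang artefacts so statistics cover the phase
    exactly; without it the raw painted map is returned (painted background
    voxels keep their values, unpainted voxels are NaN).

    Requires isotropic calibration (the sphere model is meaningless
    otherwise) and a non-empty mask.
    """
    if not mask.calibration.is_isotropic:
        raise ValueError("local thickness requires isotropic voxel calibration")
    if mask.foreground_count == 0:
        raise ValueError("local thickness of an empty mask is undefined")
    spacing = mask.calibration.spacing[0]
    d2 = _squared_edt(mask.voxels)
    ridge = distance_ridge(mask)
    shape = mask.shape
    out = np.full(shape, -np.inf)
    templates: dict[int, tuple[int, np.ndarray]] = {}
    centres = np.argwhere(ridge)
    radii2 = d2[ridge]
    for (z, y, x), r2 in zip(centres, radii2):
        r2 = int(r2)
        if r2 not in templates:
            templates[r2] = _ball_template(r2)
        R, ball = templates[r2]
        lo = (z - R, y - R, x - R)
        hi = (z + R + 1, y + R + 1, x + R + 1)
        diameter = (2.0 * np.sqrt(r2) - 1.0) * spacing
        dst = tuple(slice(max(l, 0), min(h, n)) for l, h, n in zip(lo, hi, shape))
        src = tuple(
            slice(max(-l, 0), (2 * R + 1) - max(h - n, 0)) for l, h, n in zip(lo, hi, shape)
        )
        sub = out[dst]
        np.maximum(sub, np.where(ball[src], diameter, -np.inf), out=sub)
    if mask_artefacts:
        out[~mask.voxels] = np.nan  # drop sphere overhang outside the phase
    out[np.isneginf(out)] = np.nan
    return ThicknessMap(out, mask.calibration, phase="foreground")


def spacing_map(mask: BinaryMask, mask_artefacts: bool = True) -> ThicknessMap:
    """Local thickness of the background phase (trabecular separation)."""
    inverted = mask.inverted()
    if inverted.foreground_count == 0:
        raise ValueError("spacing map undefined: mask has no background")
    tm = local_thickness(inverted, mask_artefacts=mask_artefacts)
    return ThicknessMap(tm.map, tm.calibration, phase="background")


def thickness_stats(tmap: ThicknessMap) -> ThicknessStats:
    """Mean / SD / max over finite map voxels (NaN background excluded)."""
    finite = tmap.map[np.isfinite(tmap.map)]
    if finite.size == 0:
        raise ValueError("thickness map has no finite voxels")
    return ThicknessStats(
        mean=float(finite.mean()), sd=float(finite.std()), max=float(finite.max())
    )
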