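"""Seedable synthetic 3D structures with analytically known morphometrics.

Every phantom is generated deterministically from its spec (and seed, where
stochastic) and carries an *expectation record*: the analytic values —
Euler characteristic, voxel counts, thickness, anisotropy and EF signs,
fractal dimension — that the measurement modules must reproduce.  The test
suite validates each record against the corresponding module, replacing any
dependence on downloaded specimen data.

Digitisation rule: a voxel is foreground iff its centre satisfies the
analytic inequality of the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np
from scipy import ndimage

from .core import BinaryMask, Calibration, Image3D

__all__ = ["PhantomSpec", "Phantom", "KINDS", "generate"]

KINDS = (
    "ball",
    "shell",
    "slab",
    "slab_stack",
    "rod_lattice",
    "ring",
    "menger",
    "two_particles",
    "blurred_noise",
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic structure.

    ``params`` holds the per-kind geometry (see the ``_make_*`` builders for
    the accepted keys and defaults); ``spacing`` is the isotropic voxel size.
    """

    kind: str
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.0
    unit: str = ""
    rng_seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected one of {KINDS}")


@dataclass
class Phantom:
    data: Union[BinaryMask, Image3D]
    expected: dict[str, Any]

    @property
    def mask(self) -> BinaryMask:
        if not isinstance(self.data, BinaryMask):
            raise TypeError("this phantom is a greyscale image, not a mask")
        return self.data


def _centre_grid(shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # integer (voxel-centred) origin so digitised radii match their analytic
    # values; with a half-integer centre no voxel sits at distance 0
    z, y, x = np.indices(shape).astype(float)
    cz, cy, cx = ((n - 1) // 2 for n in shape)
    return z - cz, y - cy, x - cx


def _make_ball(shape, p) -> tuple[np.ndarray, dict]:
    r = p.get("radius", min(shape) // 2 - 2)
    if 2 * r + 1 > min(shape):
        raise ValueError(f"ball radius {r} does not fit in shape {shape}")
    z, y, x = _centre_grid(shape)
    vox = z * z + y * y + x * x <= r * r
    return vox, {
        "chi": 1,
        "radius_vox": r,
        "max_thickness_vox": 2 * r,
        "ef_sign": "zero",
        "fractal_dimension": 3.0,
    }


def _make_shell(shape, p) -> tuple[np.ndarray, dict]:
    outer = p.get("outer", min(shape) // 2 - 2)
    inner = p.get("inner", max(outer - 4, 1))
    if not 0 < inner < outer:
        raise ValueError("shell needs 0 < inner < outer")
    z, y, x = _centre_grid(shape)
    d2 = z * z + y * y + x * x
    vox = (d2 <= outer * outer) & (d2 > inner * inner)
    return vox, {"chi": 2, "outer_vox": outer, "inner_vox": inner}


def _make_slab(shape, p) -> tuple[np.ndarray, dict]:
    t = p.get("thickness", 5)
    if t < 1 or t > shape[0]:
        raise ValueError(f"slab thickness {t} does not fit along z in shape {shape}")
    z0 = (shape[0] - t) // 2
    vox = np.zeros(shape, dtype=bool)
    vox[z0 : z0 + t] = True
    return vox, {"chi": 1, "thickness_vox": t, "bv_voxels": t * shape[1] * shape[2]}


def _make_slab_stack(shape, p) -> tuple[np.ndarray, dict]:
    t = p.get("thickness", 4)
    gap = p.get("gap", 8)
    period = t + gap
    vox = np.zeros(shape, dtype=bool)
    n_plates = 0
    z = 0
    while z + t <= shape[0]:
        vox[z : z + t] = True
        n_plates += 1
        z += period
    if n_plates < 2:
        raise ValueError("slab_stack needs room for at least two plates")
    return vox, {
        "chi": n_plates,
        "n_plates": n_plates,
        "thickness_vox": t,
        "gap_vox": gap,
        "da_sign": "anisotropic",
        "ef_sign": "plate",
        "normal_axis": 0,
    }


def _make_rod_lattice(shape, p) -> tuple[np.ndarray, dict]:
    r = p.get("radius", 3)
    pitch = p.get("pitch", 16)
    z, y, x = np.indices(shape).astype(float)
    vox = np.zeros(shape, dtype=bool)
    n_rods = 0
    for cy in np.arange(pitch / 2, shape[1], pitch):
        for cx in np.arange(pitch / 2, shape[2], pitch):
            vox |= (y - cy) ** 2 + (x - cx) ** 2 <= r * r
            n_rods += 1
    if n_rods < 1:
        raise ValueError("rod_lattice pitch leaves no rods in the volume")
    return vox, {
        "chi": n_rods,
        "n_rods": n_rods,
        "radius_vox": r,
        "da_sign": "anisotropic",
        "ef_sign": "rod",
        "rod_axis": 0,
    }


def _make_ring(shape, p) -> tuple[np.ndarray, dict]:
    outer = p.get("outer", min(shape[1], shape[2]) // 2 - 2)
    width = p.get("width", max(outer // 3, 1))
    height = p.get("height", width)
    z, y, x = _centre_grid(shape)
    planar = np.maximum(np.abs(y), np.abs(x))
    vox = (planar <= outer) & (planar > outer - width) & (np.abs(z) <= height / 2.0)
    return vox, {"chi": 0, "connectivity": 1}


def _make_menger(shape, p) -> tuple[np.ndarray, dict]:
    order = p.get("order", 4)
    n = 3**order
    if shape != (n, n, n):
        raise ValueError(f"order-{order} sponge needs shape {(n, n, n)}, got {shape}")
    idx = np.indices(shape)
    vox = np.ones(shape, dtype=bool)
    for level in range(order):
        digits = (idx // 3**level) % 3
        vox &= (digits == 1).sum(axis=0) < 2
    return vox, {
        "order": order,
        "bv_voxels": 20**order,
        "fractal_dimension": float(np.log(20) / np.log(3)),
        "box_sizes": [3**k for k in range(order)],
        "box_counts": [20 ** (order - k) for k in range(order)],
    }


def _make_two_particles(shape, p) -> tuple[np.ndarray, dict]:
    n_large = p.get("large", 10)
    n_small = p.get("small", 5)
    vox = np.zeros(shape, dtype=bool)
    vox[2, 2, 2 : 2 + n_large] = True
    vox[shape[0] - 3, shape[1] - 3, 2 : 2 + n_small] = True
    if vox.sum() != n_large + n_small:
        raise ValueError("particles overlap or clip the stack")
    return vox, {
        "chi": 2,
        "n_components": 2,
        "largest_voxels": max(n_large, n_small),
        "smallest_voxels": min(n_large, n_small),
    }


def _make_blurred_noise(shape, p, rng_seed) -> tuple[np.ndarray, dict]:
    sigma = p.get("sigma", 3.0)
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    vox = smooth >= np.median(smooth)  # 50 % threshold -> BV/TV = 0.5
    return vox, {
        "bv_tv": 0.5,
        "da_sign": "isotropic",
        "sigma_vox": sigma,
    }


def generate(spec: PhantomSpec) -> Phantom:
    """Build the phantom and its analytic expectation record.

    Deterministic for a given spec and seed.  All phantoms are binary masks;
    greyscale stacks for threshold/blur testing are obtained by scaling a
    mask (see :func:`to_greyscale`).
    """
    shape = tuple(int(n) for n in spec.shape)
    if spec.kind == "ball":
        vox, exp = _make_ball(shape, spec.params)
    elif spec.kind == "shell":
        vox, exp = _make_shell(shape, spec.params)
    elif spec.kind == "slab":
        vox, exp = _make_slab(shape, spec.params)
    elif spec.kind == "slab_stack":
        vox, exp = _make_slab_stack(shape, spec.params)
    elif spec.kind == "rod_lattice":
        vox, exp = _make_rod_lattice(shape, spec.params)
    elif spec.kind == "ring":
        vox, exp = _make_ring(shape, spec.params)
    elif spec.kind == "menger":
        vox, exp = _make_menger(shape, spec.params)
    elif spec.kind == "two_particles":
        vox, exp = _make_two_particles(shape, spec.params)
    elif spec.kind == "blurred_noise":
        vox, exp = _make_blurred_noise(shape, spec.params, spec.rng_seed)
    else:  # pragma: no cover — guarded by PhantomSpec
        raise ValueError(spec.kind)
    cal = Calibration((spec.spacing,) * 3, spec.unit)
    exp = {"kind": spec.kind, "bv_voxels": int(vox.sum()), **exp}
    return Phantom(BinaryMask(vox, cal), exp)


def to_greyscale(mask: BinaryMask, foreground: int = 200, background: int = 50, bit_depth=16) -> Image3D:
    """Render a mask as a two-level greyscale stack (for threshold tests)."""
    vox = np.where(mask.voxels, foreground, background)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return Image3D(vox.astype(dtype), bit_depth, mask.calibration)
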