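"""Connectivity analysis from the Euler characteristic of a binary volume.

The foreground is modelled as the union of closed unit voxel cubes, the
continuous analogue of 26-connected digital foreground (two cubes meeting
only at a corner share that corner point).  The Euler characteristic is

    chi = V - E + F - C

over the *distinct* vertices, edges, faces and cubes of that union.  The
implementation sums a 256-entry octant lookup table over all 2x2x2 voxel
neighbourhoods; each cell of the complex is owned by its minimal lattice
corner, so the octant sum reproduces V - E + F - C exactly.

Because a scanned specimen continues beyond the image, chi of the stack
overcounts structure lying on the stack boundary.  The edge correction
weights every cell by 1/2 per bounding-box plane that contains it (1/2 on a
face, 1/4 on an edge, 1/8 at a corner of the box) — the weight of a cell
shared between abutting subvolumes when tiling space — giving the corrected
Euler characteristic chi - delta_chi at exact 1/8 granularity.

Connectivity follows as Conn = 1 - (chi - delta_chi), and connectivity
density as Conn.D = Conn / TV with TV the full calibrated stack volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product

import numpy as np

from .core import BinaryMask

__all__ = [
    "EulerResult",
    "ConnectivityResult",
    "euler_characteristic",
    "edge_correction",
    "corrected_euler",
    "connectivity_from_chi",
    "connectivity_density",
    "octant_lut",
]


def _build_octant_lut() -> np.ndarray:
    """Per-octant chi contributions for all 256 2x2x2 configurations.

    The octant around lattice vertex v holds the 8 voxels at offsets
    {-1, 0}^3 (bit i of the configuration = voxel at offset
    ``(b2-1, b1-1, b0-1)`` for bits b of i, z-major).  Vertex v owns: itself,
    the 3 edges leaving it in +z/+y/+x, the 3 faces and the 1 cube whose
    minimal corner is v — all of whose incident voxels lie in the octant.
    """

    def bit(cfg: int, dz: int, dy: int, dx: int) -> int:
        # offset coordinates in {-1, 0} map to bit positions via o + 1
        return (cfg >> (((dz + 1) << 2) | ((dy + 1) << 1) | (dx + 1))) & 1

    lut = np.zeros(256, dtype=np.int32)
    offsets = [(-1, 0)] * 3
    for cfg in range(256):
        chi = 0
        # vertex v: present iff any incident voxel is foreground
        if any(bit(cfg, dz, dy, dx) for dz, dy, dx in product(*offsets)):
            chi += 1
        # edges from v along each axis: incident voxels have offset 0 on that
        # axis and {-1, 0} on the others
        for axis in range(3):
            others = [[0] if a == axis else [-1, 0] for a in range(3)]
            if any(bit(cfg, dz, dy, dx) for dz, dy, dx in product(*others)):
                chi -= 1
        # faces with minimal corner v: offset 0 on both spanned axes
        for axis in range(3):  # axis = the normal direction
            others = [[-1, 0] if a == axis else [0] for a in range(3)]
            if any(bit(cfg, dz, dy, dx) for dz, dy, dx in product(*others)):
                chi += 1
        # the cube with minimal corner v
        if bit(cfg, 0, 0, 0):
            chi -= 1
        lut[cfg] = chi
    return lut


_OCTANT_LUT = _build_octant_lut()


def octant_lut() -> np.ndarray:
    """The programmatically generated 256-entry octant table (copy)."""
    return _OCTANT_LUT.copy()


def _octant_configs(voxels: np.ndarray) -> np.ndarray:
    """Configuration index of every 2x2x2 neighbourhood (one per lattice vertex)."""
    z, y, x = voxels.shape
    m = np.pad(voxels, 1).astype(np.uint8)
    cfg = np.zeros((z + 1, y + 1, x + 1), dtype=np.uint8)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                piece = m[dz : dz + z + 1, dy : dy + y + 1, dx : dx + x + 1]
                cfg |= piece << ((dz << 2) | (dy << 1) | dx)
    return cfg


def euler_characteristic(mask: BinaryMask) -> int:
    """chi of the foreground (26-connected convention) by octant-table sum."""
    cfg = _octant_configs(mask.voxels)
    return int(_OCTANT_LUT[cfg].sum(dtype=np.int64))


def _weighted_cell_sums(voxels: np.ndarray) -> tuple[int, int]:
    """(8*chi, 8*chi_corrected) from distinct-cell counts of the cube union.

    Cells spanning axis subset S sit at voxel-aligned positions along axes in
    S and lattice positions along the rest; presence is the OR of their
    incident voxels.  A cell is contained in a bounding-box plane only along
    a non-spanned axis whose lattice coordinate is extremal, and each such
    plane halves its tiling weight.
    """
    dims = voxels.shape
    m = np.pad(voxels, 1)
    total8 = 0
    corrected8 = 0
    for spanned in product((False, True), repeat=3):
        ndim_cell = sum(spanned)
        sign = 1 if ndim_cell % 2 == 0 else -1  # vertices +, edges -, faces +, cubes -
        # presence = OR over incident voxels
        choices = [((1,) if sp else (0, 1)) for sp in spanned]
        sizes = [dims[a] if sp else dims[a] + 1 for a, sp in enumerate(spanned)]
        present = np.zeros(sizes, dtype=bool)
        for off in product(*choices):
            sl = tuple(slice(o, o + s) for o, s in zip(off, sizes))
            present |= m[sl].astype(bool)
        # halvings: one per non-spanned axis at an extremal lattice coordinate
        halvings = np.zeros(sizes, dtype=np.int8)
        for a, sp in enumerate(spanned):
            if sp:
                continue
            vec = np.zeros(sizes[a], dtype=np.int8)
            vec[0] = vec[-1] = 1
            shape = [1, 1, 1]
            shape[a] = sizes[a]
            halvings = halvings + vec.reshape(shape)
        n_cells = int(present.sum(dtype=np.int64))
        weighted = int((np.asarray(8 >> halvings, dtype=np.int64) * present).sum(dtype=np.int64))
        total8 += sign * 8 * n_cells
        corrected8 += sign * weighted
    return total8, corrected8


@dataclass(frozen=True)
class EulerResult:
    """chi, the boundary term delta_chi and the corrected chi - delta_chi."""

    chi: int
    delta_chi: Fraction
    chi_corrected: Fraction

    def __post_init__(self) -> None:
        if self.chi - self.delta_chi != self.chi_corrected:
            raise ValueError("chi_corrected must equal chi - delta_chi exactly")


@dataclass(frozen=True)
class ConnectivityResult:
    """Conn = 1 - (chi - delta_chi) and Conn.D = Conn / TV."""

    connectivity: Fraction
    conn_density: float
    tv: float
    euler: EulerResult | None = None


def corrected_euler(mask: BinaryMask) -> EulerResult:
    """chi with the Odgaard-style boundary correction, exact in eighths."""
    total8, corrected8 = _weighted_cell_sums(mask.voxels)
    chi = total8 // 8
    chi_corrected = Fraction(corrected8, 8)
    return EulerResult(chi=chi, delta_chi=chi - chi_corrected, chi_corrected=chi_corrected)


def edge_correction(mask: BinaryMask) -> Fraction:
    """delta_chi: the estimated chi contribution of structure cut by the
    stack boundary (0 when no foreground touches any boundary face)."""
    return corrected_euler(mask).delta_chi


def connectivity_from_chi(chi_corrected, tv: float, euler: EulerResult | None = None) -> ConnectivityResult:
    """Conn and Conn.D from a corrected Euler characteristic and total volume."""
    if tv <= 0:
        raise ValueError("total volume must be positive")
    conn = 1 - Fraction(chi_corrected)
    return ConnectivityResult(connectivity=conn, conn_density=float(conn) / tv, tv=float(tv), euler=euler)


def connectivity_density(mask: BinaryMask) -> ConnectivityResult:
    """Full connectivity analysis of a (purified) mask.

    TV is the whole-stack volume in calibrated units cubed.  For Conn to
    count trabecular connections the mask should hold a single purified
    particle; the computation itself accepts any mask.
    """
    euler = corrected_euler(mask)
    return connectivity_from_chi(euler.chi_corrected, mask.total_volume, euler)
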