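"""Degree of anisotropy (DA) by mean-intercept-length (MIL) sampling.

For each of ``n_directions`` uniformly random unit vectors, a bundle of
parallel test lines is cast through the volume and walked at a fixed
sampling increment.  The mean intercept length along direction w is the
total bone path length divided by the number of bone intercepts (maximal
foreground runs; runs truncated by the volume border count as half).  The
point cloud ``w * MIL(w)`` is fitted with a least-squares ellipsoid whose
extreme radii give ``DA = 1 - r_min / r_max``: 0 for an isotropic fabric,
approaching 1 for strongly oriented structure.

MIL sampling is stochastic; results carry seed-to-seed spread that shrinks
with more directions and lines.  The *recommended minimums* are 2000
directions, 10000 lines per direction and a 1.73-voxel increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask

__all__ = [
    "MILPointCloud",
    "EllipsoidModel",
    "AnisotropyResult",
    "RECOMMENDED_MINIMUMS",
    "mil_for_direction",
    "sample_mil",
    "fit_ellipsoid",
    "degree_of_anisotropy",
]

#: directions, lines per direction, sampling increment (voxels)
RECOMMENDED_MINIMUMS = {"n_directions": 2000, "n_lines": 10000, "increment": 1.73}


@dataclass
class MILPointCloud:
    """One point per sampled direction: the direction scaled by its MIL."""

    points: np.ndarray  # (n, 3) calibrated lengths
    n_directions: int
    n_lines_per_direction: int
    sampling_increment: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if not (np.linalg.norm(self.points, axis=1) > 0).all():
            raise ValueError("all MIL values must be positive")


@dataclass
class EllipsoidModel:
    """Ellipsoid with semi-axes sorted ascending and orthonormal orientation."""

    centre: np.ndarray
    semi_axes: tuple[float, float, float]  # a <= b <= c
    orientation: np.ndarray  # columns are the axis directions, det +1

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float)
        a, b, c = self.semi_axes
        if not (0 < a <= b <= c):
            raise ValueError(f"semi-axes must be positive ascending, got {self.semi_axes}")
        q = np.asarray(self.orientation, dtype=float)
        if not np.allclose(q.T @ q, np.eye(3), atol=1e-8) or np.linalg.det(q) < 0:
            raise ValueError("orientation must be orthonormal with determinant +1")
        self.orientation = q

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


@dataclass(frozen=True)
class AnisotropyResult:
    da: float
    ellipsoid: EllipsoidModel
    radii: tuple[float, float, float]  # (r_min, r_mid, r_max)

    def __post_init__(self) -> None:
        r_min, _, r_max = self.radii
        if abs(self.da - (1.0 - r_min / r_max)) > 1e-12:
            raise ValueError("da must equal 1 - r_min/r_max")


def _orthonormal_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    return u, np.cross(w, u)


def mil_for_direction(
    mask: BinaryMask,
    direction,
    n_lines: int,
    increment: float,
    rng: np.random.Generator,
) -> float | None:
    """Mean intercept length along one unit direction, or None if the line
    bundle crosses no foreground run.

    Lines are anchored on a jittered grid covering the stack cross-section
    through the volume centre and walked at ``increment`` voxels; foreground
    runs truncated by the volume border count as half an intercept.
    """
    w = np.asarray(direction, dtype=float)
    w = w / np.linalg.norm(w)
    spacing = mask.calibration.spacing[0]
    shape = np.array(mask.shape, dtype=float)
    extent = shape * spacing
    centre = extent / 2.0
    radius = float(np.linalg.norm(extent)) / 2.0
    step = increment * spacing
    n_steps = max(int(np.ceil(2.0 * radius / step)), 2)
    taus = (np.arange(n_steps) - (n_steps - 1) / 2.0) * step
    grid_n = int(np.ceil(np.sqrt(n_lines)))
    cell = 2.0 * radius / grid_n
    voxels = mask.voxels

    u, v = _orthonormal_basis(w)
    gi, gj = np.meshgrid(np.arange(grid_n), np.arange(grid_n), indexing="ij")
    anchors = np.stack([gi.ravel(), gj.ravel()], axis=1)[:n_lines].astype(float)
    offsets = (anchors + rng.random((len(anchors), 2))) * cell - radius
    origin = centre + offsets[:, :1] * u + offsets[:, 1:2] * v  # (L, 3)
    pos = origin[:, None, :] + taus[None, :, None] * w  # (L, S, 3)
    idx = np.floor(pos / spacing).astype(np.int64)
    inside = ((idx >= 0) & (idx < np.array(mask.shape))).all(axis=2)
    fg = np.zeros(inside.shape, dtype=bool)
    ii = idx[inside]
    fg[inside] = voxels[ii[:, 0], ii[:, 1], ii[:, 2]]

    # run/boundary bookkeeping: runs abutting the volume edge count half
    padded = np.zeros((fg.shape[0], fg.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = fg
    diff = np.diff(padded, axis=1)
    start_l, start_s = np.nonzero(diff == 1)
    end_l, end_s = np.nonzero(diff == -1)
    if len(start_s) == 0:
        return None
    end_s = end_s - 1  # inclusive last sample of each run
    open_left = (start_s == 0) | ~inside[start_l, np.maximum(start_s - 1, 0)]
    open_right = (end_s == fg.shape[1] - 1) | ~inside[
        end_l, np.minimum(end_s + 1, fg.shape[1] - 1)
    ]
    weights = np.where(open_left | open_right, 0.5, 1.0)
    n_intercepts = float(weights.sum())
    if n_intercepts <= 0:
        return None
    return float(fg.sum() * step / n_intercepts)


def sample_mil(
    mask: BinaryMask,
    n_directions: int = 2000,
    n_lines: int = 10000,
    increment: float = 1.73,
    rng_seed: int | None = None,
) -> MILPointCloud:
    """Sample the MIL point cloud of a binary structure.

    Directions are drawn uniformly on the sphere (normalised Gaussian
    triples).  Per direction, line anchors sit on a jittered grid covering
    the stack cross-section through the volume centre; each line is walked
    at ``increment`` voxels.  Directions that cross no bone/marrow interface
    are dropped; fewer than 9 surviving directions is an error.
    """
    if not mask.calibration.is_isotropic:
        raise ValueError("MIL sampling requires isotropic voxel calibration")
    n_fg = mask.foreground_count
    if n_fg == 0 or n_fg == mask.voxels.size:
        raise ValueError("mask must contain both foreground and background")
    rng = np.random.default_rng(rng_seed)
    points = []
    for _ in range(n_directions):
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        mil = mil_for_direction(mask, w, n_lines, increment, rng)
        if mil is not None:
            points.append(w * mil)

    if len(points) < 9:
        raise ValueError(f"only {len(points)} directions produced intercepts; need at least 9")
    return MILPointCloud(np.array(points), len(points), n_lines, increment)


def fit_ellipsoid(points: np.ndarray) -> EllipsoidModel:
    """Least-squares quadric fit constrained to an ellipsoid.

    Solves ``x'Ax + 2b'x = 1`` for the 9 quadric parameters, recentres at
    ``-A^-1 b`` and eigendecomposes the recentred form.  Requires at least 9
    points in general position whose best-fit quadric has positive-definite
    form (otherwise the data do not determine an ellipsoid).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 9:
        raise ValueError("need at least 9 points of shape (n, 3)")
    x, y, z = pts.T
    design = np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z, 2 * x, 2 * y, 2 * z]
    )
    sol, _, rank, _ = np.linalg.lstsq(design, np.ones(len(pts)), rcond=None)
    if rank < 9:
        raise ValueError("degenerate point configuration: quadric underdetermined")
    a3 = np.array(
        [[sol[0], sol[3], sol[4]], [sol[3], sol[1], sol[5]], [sol[4], sol[5], sol[2]]]
    )
    b = sol[6:9]
    try:
        centre = -np.linalg.solve(a3, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("fitted quadric is singular; not an ellipsoid") from exc
    # recentred form: y' (A/k) y = 1 with k = 1 + b'A^-1 b
    k = 1.0 + b @ -centre
    eigvals, eigvecs = np.linalg.eigh(a3 / k)
    if (eigvals <= 0).any():
        raise ValueError("fitted quadric is not an ellipsoid")
    radii = 1.0 / np.sqrt(eigvals)  # eigh ascending eigvals -> radii descending
    order = np.argsort(radii)
    radii = radii[order]
    q = eigvecs[:, order]
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return EllipsoidModel(centre=centre, semi_axes=tuple(radii), orientation=q)


def degree_of_anisotropy(
    mask: BinaryMask,
    n_directions: int = 2000,
    n_lines: int = 10000,
    increment: float = 1.73,
    rng_seed: int | None = None,
) -> AnisotropyResult:
    """DA = 1 - r_min/r_max of the MIL-cloud ellipsoid.

    The default parameters are the recommended minimums.  The MIL cloud is
    augmented with its antipodes before fitting (MIL is symmetric under
    direction reversal), which pins the quadric centre to the origin.
    """
    cloud = sample_mil(mask, n_directions, n_lines, increment, rng_seed)
    ellipsoid = fit_ellipsoid(np.vstack([cloud.points, -cloud.points]))
    radii = ellipsoid.semi_axes
    return AnisotropyResult(da=1.0 - radii[0] / radii[2], ellipsoid=ellipsoid, radii=radii)
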