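"""Calibrated 3D image containers, TIFF stack I/O and the shared results table.

Conventions used throughout the package:

* voxel grids are indexed ``(z, y, x)`` — axis 0 is the stack (page) axis;
* physical units are carried in :class:`Calibration` and never converted;
  every measurement reports in the calibration unit;
* float "map" images (thickness, EF) encode background as NaN so that
  downstream statistics can exclude it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "Image3D",
    "BinaryMask",
    "ResultsTable",
    "MEASURES",
    "read_stack",
    "write_stack",
    "write_map",
]

#: Isotropy is declared when max/min spacing agree to this relative tolerance.
ISOTROPY_RTOL = 1e-6


@dataclass(frozen=True)
class Calibration:
    """Physical voxel size, per axis, in ``unit``.

    ``spacing`` is ordered ``(z, y, x)`` like the voxel grid.
    """

    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    unit: str = ""

    def __post_init__(self) -> None:
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(not np.isfinite(s) or s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive finite values, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)

    @property
    def is_isotropic(self) -> bool:
        return (max(self.spacing) / min(self.spacing) - 1.0) < ISOTROPY_RTOL

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in ``unit`` cubed."""
        return float(np.prod(self.spacing))

    def scaled(self, factor: float) -> "Calibration":
        return Calibration(tuple(s * factor for s in self.spacing), self.unit)


_BIT_DEPTHS = {8: np.uint8, 16: np.uint16, "float": np.float32}


@dataclass
class Image3D:
    """A calibrated 3D scalar field (greyscale stack), indexed ``(z, y, x)``."""

    voxels: np.ndarray
    bit_depth: Union[int, str] = 16
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or 0 in self.voxels.shape:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.voxels.shape}")
        if self.bit_depth not in _BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {sorted(map(str, _BIT_DEPTHS))}")
        if self.bit_depth != "float":
            if not np.issubdtype(self.voxels.dtype, np.integer):
                raise ValueError("integer bit depth requires an integer voxel dtype")
            self.voxels = self.voxels.astype(_BIT_DEPTHS[self.bit_depth])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def max_representable(self) -> float:
        if self.bit_depth == "float":
            return float(np.finfo(np.float32).max)
        return float(np.iinfo(_BIT_DEPTHS[self.bit_depth]).max)

    def histogram(self) -> np.ndarray:
        """Full-stack intensity histogram (one bin per representable level)."""
        if self.bit_depth == "float":
            raise ValueError("per-level histogram is defined for integer bit depths only")
        n_bins = int(self.max_representable) + 1
        return np.bincount(self.voxels.ravel(), minlength=n_bins)


@dataclass
class BinaryMask:
    """3D boolean field; ``True`` (foreground) = bone."""

    voxels: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or 0 in self.voxels.shape:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.voxels.shape}")
        if self.voxels.dtype != bool:
            vals = np.unique(self.voxels)
            if not np.isin(vals, (0, 1)).all() and not np.isin(vals, (0, 255)).all():
                raise ValueError("mask voxels must be two-valued (0/1 or 0/255)")
            self.voxels = self.voxels != 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def total_volume(self) -> float:
        """Whole-stack volume (TV) in calibrated units cubed."""
        return self.voxels.size * self.calibration.voxel_volume

    def inverted(self) -> "BinaryMask":
        return BinaryMask(~self.voxels, self.calibration)


#: Controlled vocabulary for the results table, in canonical report order.
MEASURES: tuple[str, ...] = (
    "Threshold lower",
    "Threshold upper",
    "DA",
    "BV",
    "TV",
    "BV/TV",
    "Surface area",
    "Tb.Th Mean",
    "Tb.Th Std. Dev.",
    "Tb.Th Max",
    "Tb.Sp Mean",
    "Tb.Sp Std. Dev.",
    "Tb.Sp Max",
    "Median EF",
    "Max EF",
    "Min EF",
    "Euler char (χ)",
    "Corr. Euler (χ − Δχ)",
    "Connectivity",
    "Conn.D",
    "Fractal dimension",
)

_CSV_COLUMNS = ["Image", "Measure", "Value", "Unit"]


class ResultsTable:
    """Accumulates (image, measure, value, unit) rows; exportable as CSV.

    Rows keep insertion order; values may be NaN only where a measure is
    genuinely undefined (e.g. EF of an uncovered phase).
    """

    def __init__(self, rows: Iterable[tuple[str, str, float, str]] = ()) -> None:
        self._rows: list[tuple[str, str, float, str]] = []
        for label, measure, value, unit in rows:
            self.append(label, measure, value, unit)

    def append(self, label: str, measure: str, value: float, unit: str = "") -> "ResultsTable":
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        self._rows.append((str(label), measure, float(value), str(unit)))
        return self

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResultsTable):
            return NotImplemented
        if len(self._rows) != len(other._rows):
            return False
        for a, b in zip(self._rows, other._rows):
            if a[:2] != b[:2] or a[3] != b[3]:
                return False
            if not (a[2] == b[2] or (np.isnan(a[2]) and np.isnan(b[2]))):
                return False
        return True

    def value(self, measure: str, label: str | None = None) -> float:
        """Last recorded value for ``measure`` (optionally for a given image)."""
        for row in reversed(self._rows):
            if row[1] == measure and (label is None or row[0] == label):
                return row[2]
        raise KeyError(measure)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=_CSV_COLUMNS)

    def to_csv(self, path_or_buf=None) -> str | None:
        # str(float) round-trips exactly in float64, keeping CSV I/O lossless
        df = self.to_dataframe()
        df["Value"] = [repr(v) for v in df["Value"]]
        return df.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ResultsTable":
        df = pd.read_csv(path_or_buf, keep_default_na=False, dtype=str)
        if list(df.columns) != _CSV_COLUMNS:
            raise ValueError(f"expected columns {_CSV_COLUMNS}, got {list(df.columns)}")
        rows = [
            (r.Image, r.Measure, float(r.Value), r.Unit)
            for r in df.itertuples(index=False)
        ]
        return cls(rows)


# ---------------------------------------------------------------------------
# TIFF stack I/O
# ---------------------------------------------------------------------------

_DTYPE_TO_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16, np.dtype(np.float32): "float"}


def _resolution_to_spacing(page) -> tuple[float | None, float | None]:
    """Return (dy, dx) in resolution units from a TIFF page, or Nones."""
    tags = page.tags
    out = []
    for name in ("YResolution", "XResolution"):
        tag = tags.get(name)
        if tag is None:
            out.append(None)
            continue
        num, den = tag.value if isinstance(tag.value, tuple) else (tag.value, 1)
        out.append(den / num if num else None)
    return out[0], out[1]


def read_stack(path) -> Image3D:
    """Read a multi-page TIFF as a calibrated :class:`Image3D`.

    Calibration is taken from the TIFF X/Y resolution tags and, when the file
    carries ImageJ metadata, the ``spacing``/``unit`` fields for the z axis.
    Missing tags fall back to unit spacing with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        voxels = series.asarray()
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxels.ndim != 3:
            raise ValueError(f"{path}: expected a 3D stack, got shape {voxels.shape}")
        if voxels.dtype not in _DTYPE_TO_DEPTH:
            raise ValueError(f"{path}: unsupported sample format {voxels.dtype}")
        dy, dx = _resolution_to_spacing(tif.pages[0])
        meta = tif.imagej_metadata or {}
        dz = meta.get("spacing")
        unit = meta.get("unit", "")
    if dx is None or dy is None:
        warnings.warn(f"{path}: no TIFF resolution tags; assuming unit voxel spacing")
        dx = 1.0 if dx is None else dx
        dy = 1.0 if dy is None else dy
    if dz is None:
        dz = dx  # stacks are commonly written isotropic; documented fallback
    return Image3D(voxels, _DTYPE_TO_DEPTH[voxels.dtype], Calibration((float(dz), float(dy), float(dx)), unit))


def write_stack(image: Image3D, path) -> None:
    """Write an :class:`Image3D` as a multi-page TIFF with calibration tags."""
    dz, dy, dx = image.calibration.spacing
    tifffile.imwrite(
        Path(path),
        np.asarray(image.voxels),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": image.calibration.unit, "axes": "ZYX"},
    )


def write_map(map_voxels: np.ndarray, path, calibration: Calibration | None = None) -> None:
    """Write a float map (NaN background) as a 32-bit float multi-page TIFF."""
    arr = np.asarray(map_voxels, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D float map, got shape {arr.shape}")
    cal = calibration or Calibration()
    write_stack(Image3D(arr, "float", cal), path)
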