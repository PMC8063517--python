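"""End-to-end orchestration of the morphometry pipeline.

A pipeline is a pure function of (input bytes, configuration, seed):
steps execute in the configured order, append their statistics to one
:class:`~trabecula3d.core.ResultsTable` and write the table as CSV.
Repeated runs with the same inputs produce byte-identical output.

The classic measurement sequence mirrors interactive practice: smooth the
greyscale stack, auto-threshold and binarise, then measure anisotropy,
volume fraction, thickness and ellipsoid factor on the thresholded mask;
purify before connectivity so the Euler characteristic sees one particle.

Configuration is a flat INI-style text file::

    [pipeline]
    input = stack.tif
    label = stack
    output = results.csv
    seed = 42
    steps = blur, threshold, anisotropy, fraction, thickness, ef, purify, connectivity

    [blur]
    sigma = 2,2,2

Every CLI flag has a config twin.  The single global seed fans out to
per-step seeds derived from the step name, so adding a step never perturbs
the randomness of earlier ones.
"""

from __future__ import annotations

import configparser
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import anisotropy as aniso
from . import ellipsoid_factor as ef_mod
from . import fractal as fractal_mod
from . import fraction_surface, preprocess, thickness, topology
from .core import BinaryMask, Image3D, ResultsTable, read_stack, write_map

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STEP_NAMES"]

STEP_NAMES = (
    "blur",
    "threshold",
    "purify",
    "connectivity",
    "fraction",
    "surface-area",
    "thickness",
    "anisotropy",
    "ef",
    "fractal",
)


class PipelineError(RuntimeError):
    def __init__(self, step: str, cause: Exception):
        super().__init__(f"pipeline step {step!r} failed: {cause}")
        self.step = step


@dataclass
class PipelineConfig:
    input: str
    steps: list[tuple[str, dict]]
    output: str = "results.csv"
    label: str | None = None
    rng_seed: int = 0
    map_prefix: str | None = None  # where thickness/EF maps are written

    def __post_init__(self) -> None:
        for name, params in self.steps:
            if name not in STEP_NAMES:
                raise ValueError(f"unknown pipeline step {name!r}; expected one of {STEP_NAMES}")
            _validate_step_params(name, params)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        if "pipeline" not in parser:
            raise ValueError(f"{path}: missing [pipeline] section")
        top = parser["pipeline"]
        step_names = [s.strip() for s in top.get("steps", "").split(",") if s.strip()]
        steps = [(name, dict(parser[name]) if name in parser else {}) for name in step_names]
        return cls(
            input=top["input"],
            steps=steps,
            output=top.get("output", "results.csv"),
            label=top.get("label"),
            rng_seed=int(top.get("seed", "0")),
            map_prefix=top.get("map_prefix"),
        )


_STEP_PARAMS = {
    "blur": {"sigma"},
    "threshold": set(),
    "purify": set(),
    "connectivity": set(),
    "fraction": set(),
    "surface-area": set(),
    "thickness": {"mask_artefacts", "maps"},
    "anisotropy": {"directions", "lines", "increment"},
    "ef": {
        "nvectors", "vector_increment", "skip_ratio", "contact_sensitivity",
        "max_iterations", "max_drift", "runs", "weighted_average_n",
        "seed_on_distance_ridge", "distance_threshold", "seed_on_topology",
    },
    "fractal": {"sizes", "jitter"},
}


def _validate_step_params(name: str, params: dict) -> None:
    unknown = set(params) - _STEP_PARAMS[name]
    if unknown:
        raise ValueError(f"step {name!r}: unknown parameters {sorted(unknown)}")


def step_seed(global_seed: int, step: str) -> int:
    """Stable per-step seed derived from the global seed and step name."""
    return zlib.crc32(f"{global_seed}:{step}".encode()) & 0x7FFFFFFF


def _as_bool(v, default=True) -> bool:
    if v is None:
        return default
    if isinstance(v, bool):
        return v
    return str(v).strip().lower() in ("1", "true", "yes", "on")


@dataclass
class _State:
    label: str
    image: Image3D | None = None
    mask: BinaryMask | None = None
    table: ResultsTable = field(default_factory=ResultsTable)
    outputs: list[Path] = field(default_factory=list)


def _need_mask(state: _State, step: str) -> BinaryMask:
    if state.mask is None:
        raise ValueError(f"step {step!r} needs a binary mask; run 'threshold' first or load a mask")
    return state.mask


def _unit(mask: BinaryMask, power: int) -> str:
    u = mask.calibration.unit
    if not u:
        return ""
    return u if power == 1 else f"{u}^{power}"


def run_pipeline(config: PipelineConfig) -> ResultsTable:
    """Execute the configured steps in order and write the results CSV.

    A failing step aborts the run with the step named and removes files the
    run had already written.
    """
    in_path = Path(config.input)
    label = config.label or in_path.stem
    state = _State(label=label)
    stack = read_stack(in_path)
    binary = set(np.unique(stack.voxels))
    if binary <= {0, 255} or binary <= {0, 1}:
        state.mask = BinaryMask(stack.voxels != 0, stack.calibration)
    state.image = stack

    current = "(setup)"
    try:
        for name, params in config.steps:
            current = name
            _run_step(state, name, params, config)
    except Exception as exc:  # noqa: BLE001 — contract: abort, clean, re-raise
        for path in state.outputs:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current, exc) from exc
    out = Path(config.output)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(state.table.to_csv())
    return state.table


def _run_step(state: _State, name: str, params: dict, config: PipelineConfig) -> None:
    seed = step_seed(config.rng_seed, name)
    t = state.table
    label = state.label
    if name == "blur":
        sigma = [float(s) for s in str(params.get("sigma", "2,2,2")).split(",")]
        sigma = sigma * 3 if len(sigma) == 1 else sigma
        state.image = preprocess.gaussian_blur_3d(state.image, sigma)
    elif name == "threshold":
        bounds = preprocess.default_threshold(state.image.histogram())
        state.mask = preprocess.to_mask(state.image, bounds)
        t.append(label, "Threshold lower", bounds.lower)
        t.append(label, "Threshold upper", bounds.upper)
    elif name == "purify":
        state.mask = preprocess.purify(_need_mask(state, name))
    elif name == "connectivity":
        mask = _need_mask(state, name)
        res = topology.connectivity_density(mask)
        t.append(label, "Euler char (χ)", res.euler.chi)
        t.append(label, "Corr. Euler (χ − Δχ)", float(res.euler.chi_corrected))
        t.append(label, "Connectivity", float(res.connectivity))
        t.append(label, "Conn.D", res.conn_density, _unit(mask, -3))
    elif name == "fraction":
        mask = _need_mask(state, name)
        res = fraction_surface.volume_fraction(mask)
        t.append(label, "BV", res.bv, _unit(mask, 3))
        t.append(label, "TV", res.tv, _unit(mask, 3))
        t.append(label, "BV/TV", res.ratio)
    elif name == "surface-area":
        mask = _need_mask(state, name)
        t.append(label, "Surface area", fraction_surface.surface_area(mask), _unit(mask, 2))
    elif name == "thickness":
        mask = _need_mask(state, name)
        artefacts = _as_bool(params.get("mask_artefacts"), True)
        maps = str(params.get("maps", "both")).lower()
        unit = _unit(mask, 1)
        if maps in ("both", "thickness"):
            tm = thickness.local_thickness(mask, mask_artefacts=artefacts)
            st = thickness.thickness_stats(tm)
            t.append(label, "Tb.Th Mean", st.mean, unit)
            t.append(label, "Tb.Th Std. Dev.", st.sd, unit)
            t.append(label, "Tb.Th Max", st.max, unit)
            _maybe_write_map(state, config, tm.map, mask, "tbth")
        if maps in ("both", "spacing"):
            sm = thickness.spacing_map(mask, mask_artefacts=artefacts)
            st = thickness.thickness_stats(sm)
            t.append(label, "Tb.Sp Mean", st.mean, unit)
            t.append(label, "Tb.Sp Std. Dev.", st.sd, unit)
            t.append(label, "Tb.Sp Max", st.max, unit)
            _maybe_write_map(state, config, sm.map, mask, "tbsp")
    elif name == "anisotropy":
        mask = _need_mask(state, name)
        res = aniso.degree_of_anisotropy(
            mask,
            n_directions=int(params.get("directions", 2000)),
            n_lines=int(params.get("lines", 10000)),
            increment=float(params.get("increment", 1.73)),
            rng_seed=seed,
        )
        t.append(label, "DA", res.da)
    elif name == "ef":
        mask = _need_mask(state, name)
        ef_params = ef_mod.EFParams(
            n_vectors=int(params.get("nvectors", 100)),
            vector_increment=float(params.get("vector_increment", 0.435)),
            skip_ratio=int(params.get("skip_ratio", 10)),
            contact_sensitivity=int(params.get("contact_sensitivity", 1)),
            max_iterations=int(params.get("max_iterations", 50)),
            max_drift=float(params.get("max_drift", 1.73)),
            runs=int(params.get("runs", 3)),
            weighted_average_n=int(params.get("weighted_average_n", 3)),
            seed_on_distance_ridge=_as_bool(params.get("seed_on_distance_ridge"), True),
            distance_threshold=float(params.get("distance_threshold", 0.6)),
            seed_on_topology=_as_bool(params.get("seed_on_topology"), False),
            rng_seed=seed,
        )
        res = ef_mod.ellipsoid_factor_map(mask, ef_params)
        t.append(label, "Median EF", res.median)
        t.append(label, "Max EF", res.max)
        t.append(label, "Min EF", res.min)
        _maybe_write_map(state, config, res.map, mask, "ef")
    elif name == "fractal":
        mask = _need_mask(state, name)
        sizes = params.get("sizes")
        sizes = (
            [int(s) for s in str(sizes).split(",")]
            if sizes
            else fractal_mod.default_box_sizes(mask.shape)
        )
        jitter = _as_bool(params.get("jitter"), False)
        series = (
            fractal_mod.box_counts_jitter(mask, sizes)
            if jitter
            else fractal_mod.box_counts(mask, sizes)
        )
        t.append(label, "Fractal dimension", fractal_mod.fractal_dimension(series))
    else:  # pragma: no cover — names validated in PipelineConfig
        raise ValueError(name)


def _maybe_write_map(state: _State, config: PipelineConfig, arr, mask: BinaryMask, tag: str) -> None:
    if config.map_prefix is None:
        return
    path = Path(f"{config.map_prefix}_{tag}.tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    write_map(arr, path, mask.calibration)
    state.outputs.append(path)
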