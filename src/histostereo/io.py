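"""File formats, study configuration, and fixture generation.

Formats: marker tables and fiber tables are CSV (µm coordinates written at
1e-6 µm precision so round-trips are lossless at that tolerance); region
contours are a small documented JSON dialect (per-section closed polygons);
study configuration is YAML; nested results are JSON.

Marker CSV header::

    specimen,region,section_index,x_um,y_um,z_um,cell_class,marker,compartment

Columns are addressed by name, so any column order is accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon

from .errors import (
    ConfigError,
    CoordinateParseError,
    MissingColumnError,
    UnknownLabelError,
)
from .probes import SamplingDesign
from .synthetic import CELL_CLASSES, COMPARTMENTS, MARKERS, ShrinkageModel

__all__ = [
    "MARKER_COLUMNS",
    "read_markers",
    "write_markers",
    "read_fibers",
    "write_fibers",
    "read_contours",
    "write_contours",
    "StudyConfig",
    "load_config",
    "make_fixtures",
]

MARKER_COLUMNS = (
    "specimen",
    "region",
    "section_index",
    "x_um",
    "y_um",
    "z_um",
    "cell_class",
    "marker",
    "compartment",
)
FIBER_COLUMNS = ("specimen", "region", "x0_um", "y0_um", "z0_um", "x1_um", "y1_um", "z1_um")

_FLOAT_FMT = "%.6f"  # 1e-6 µm precision


def write_markers(
    points: pd.DataFrame,
    path: str | Path,
    specimen: str = "synthetic",
    region: str = "region",
) -> None:
    """Write a marker table; missing bookkeeping columns are filled in."""
    df = points.copy()
    if "specimen" not in df:
        df["specimen"] = specimen
    if "region" not in df:
        df["region"] = region
    if "section_index" not in df:
        df["section_index"] = -1
    df = df[list(MARKER_COLUMNS)]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read and validate a marker table.

    Raises :class:`MissingColumnError`, :class:`CoordinateParseError` or
    :class:`UnknownLabelError` with the offending column/value named.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"marker table missing columns: {missing}")
    for col in ("x_um", "y_um", "z_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and len(df):
            bad = df.loc[vals.isna(), col].iloc[0]
            raise CoordinateParseError(f"non-numeric value {bad!r} in column {col!r}")
        df[col] = vals.astype(float)
    df["section_index"] = pd.to_numeric(df["section_index"], errors="coerce").fillna(-1).astype(int)
    for col, vocab in (
        ("cell_class", CELL_CLASSES),
        ("marker", MARKERS),
        ("compartment", COMPARTMENTS),
    ):
        bad = set(df[col].dropna().unique()) - set(vocab)
        if bad:
            raise UnknownLabelError(f"unknown {col} value(s) {sorted(bad)}; allowed: {vocab}")
    return df[list(MARKER_COLUMNS)]


def write_fibers(
    segments: np.ndarray,
    path: str | Path,
    specimen: str = "synthetic",
    region: str = "region",
) -> None:
    segs = np.asarray(segments, dtype=float).reshape(-1, 6)
    df = pd.DataFrame(segs, columns=["x0_um", "y0_um", "z0_um", "x1_um", "y1_um", "z1_um"])
    df.insert(0, "specimen", specimen)
    df.insert(1, "region", region)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fibers(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in FIBER_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"fiber table missing columns: {missing}")
    cols = ["x0_um", "y0_um", "z0_um", "x1_um", "y1_um", "z1_um"]
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() and len(df):
            raise CoordinateParseError(f"non-numeric value in column {col!r}")
        df[col] = vals
    return df[cols].to_numpy(dtype=float)


def write_contours(
    contours: Mapping[int, Polygon], path: str | Path, region: str = "region"
) -> None:
    """Write per-section closed polygons (µm) as JSON."""
    payload = {
        "region": region,
        "units": "um",
        "sections": [
            {
                "index": int(i),
                "polygon": [[float(x), float(y)] for x, y in np.asarray(p.exterior.coords)[:-1]],
            }
            for i, p in sorted(contours.items())
            if p is not None and not p.is_empty
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_contours(path: str | Path) -> dict[int, Polygon]:
    payload = json.loads(Path(path).read_text())
    if "sections" not in payload:
        raise MissingColumnError("contour JSON missing 'sections'")
    out = {}
    for sec in payload["sections"]:
        out[int(sec["index"])] = Polygon(sec["polygon"])
    return out


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class RegionConfig:
    name: str
    design: SamplingDesign
    reference_volume_mm3: float | None = None
    shape_spec: dict | None = None
    density_per_mm3: float | None = None
    label_probs: dict | None = None
    length_density_m_per_mm3: float | None = None


@dataclass
class StudyConfig:
    """Specimen metadata plus per-region sampling designs and volumes."""

    specimen: str
    processing: str = "DPX"
    regions: dict = field(default_factory=dict)  # name -> RegionConfig
    shrinkage: ShrinkageModel = field(default_factory=ShrinkageModel.identity)
    seed: int = 0
    output_dir: str = "."


_DESIGN_KEYS = {
    "section_period": int,
    "cut_thickness_um": float,
    "mounted_thickness_um": float,
    "grid_um": tuple,
    "frame_um": tuple,
    "disector_height_um": float,
    "guard_um": float,
    "ball_radius_um": float,
    "cavalieri_spacing_um": float,
}


def _parse_design(d: Mapping, where: str) -> SamplingDesign:
    kwargs = {}
    for key, value in d.items():
        if key not in _DESIGN_KEYS:
            raise ConfigError(f"{where}.design.{key}", "unknown design parameter")
        caster = _DESIGN_KEYS[key]
        kwargs[key] = tuple(float(v) for v in value) if caster is tuple else caster(value)
    try:
        return SamplingDesign(**kwargs)
    except Exception as exc:
        raise ConfigError(f"{where}.design", str(exc)) from exc


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Raises :class:`ConfigError` naming the offending key on any problem.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("<root>", "config must be a mapping")
    if "specimen" not in raw:
        raise ConfigError("specimen", "missing required key")
    if "regions" not in raw or not isinstance(raw["regions"], dict) or not raw["regions"]:
        raise ConfigError("regions", "missing or empty region mapping")

    shr_raw = raw.get("shrinkage", {}) or {}
    try:
        shrinkage = ShrinkageModel(
            xy_linear_factor=float(shr_raw.get("xy_linear_factor", 1.0)),
            z_collapse_factor=float(shr_raw.get("z_collapse_factor", 1.0)),
            truncation_fraction=float(shr_raw.get("truncation_fraction", 0.0)),
        )
    except Exception as exc:
        raise ConfigError("shrinkage", str(exc)) from exc

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed", "seed must be an integer")

    regions = {}
    for name, rcfg in raw["regions"].items():
        rcfg = rcfg or {}
        if "design" not in rcfg:
            raise ConfigError(f"regions.{name}.design", "missing sampling design")
        design = _parse_design(rcfg["design"], f"regions.{name}")
        ref = rcfg.get("reference_volume_mm3")
        if ref is not None and float(ref) <= 0:
            raise ConfigError(f"regions.{name}.reference_volume_mm3", "must be positive")
        regions[name] = RegionConfig(
            name=name,
            design=design,
            reference_volume_mm3=None if ref is None else float(ref),
            shape_spec=rcfg.get("shape"),
            density_per_mm3=rcfg.get("density_per_mm3"),
            label_probs=rcfg.get("label_probs"),
            length_density_m_per_mm3=rcfg.get("length_density_m_per_mm3"),
        )

    return StudyConfig(
        specimen=str(raw["specimen"]),
        processing=str(raw.get("processing", "DPX")),
        regions=regions,
        shrinkage=shrinkage,
        seed=seed,
        output_dir=str(raw.get("output_dir", ".")),
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir: str | Path, seed: int = 20221213) -> dict[str, Path]:
    """Write small deterministic fixtures for tests and examples.

    * ``toy_markers.csv`` — exactly 1000 neurons uniform in a 1 mm³ cube,
      labels at the IC central-nucleus mixture;
    * ``toy_fibers.csv`` — an isotropic fiber field at 1.69 m/mm³ in the
      same-volume ball;
    * ``reference_values.csv`` — the printed study quantities used by the
      worked examples;
    * ``study_config.yaml`` — a ready-to-run configuration.
    """
    from .regions import make_region
    from .reference import reference_table
    from .synthetic import simulate_fiber_field

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # exactly 1000 neurons (a Poisson field conditioned on its count)
    cube = 1000.0  # µm → 1 mm³
    xyz = rng.uniform(0.0, cube, size=(1000, 3))
    comp = rng.choice(
        np.array(COMPARTMENTS, dtype=object), size=1000, p=[0.71, 0.009, 0.14, 0.141]
    )
    pts = pd.DataFrame(
        {
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
            "cell_class": "neuron",
            "marker": "Abeta",
            "compartment": comp,
        }
    )
    markers_path = out / "toy_markers.csv"
    write_markers(pts, markers_path, specimen="synthetic", region="toy")

    # fiber field at 1.69 m/mm³ in a ball of 1 mm³
    r_um = (3.0 * 1e9 / (4.0 * np.pi)) ** (1.0 / 3.0)
    ball = make_region("toy-ball", {"ellipsoid": {"semi_axes_um": [r_um] * 3}})
    fibers = simulate_fiber_field(ball, 1.69, mean_segment_length_um=100.0, seed=seed)
    fibers_path = out / "toy_fibers.csv"
    write_fibers(fibers, fibers_path, specimen="synthetic", region="toy-ball")

    ref_path = out / "reference_values.csv"
    reference_table().to_csv(ref_path, index=False)

    config_path = out / "study_config.yaml"
    config_path.write_text(_EXAMPLE_CONFIG)
    return {
        "markers": markers_path,
        "fibers": fibers_path,
        "reference": ref_path,
        "config": config_path,
    }


_EXAMPLE_CONFIG = """\
specimen: synthetic-CN
processing: DPX
seed: 7
shrinkage:
  xy_linear_factor: 1.0
  z_collapse_factor: 0.4
  truncation_fraction: 0.0
regions:
  IC-CN:
    reference_volume_mm3: 1362.0
    density_per_mm3: 3561.0
    length_density_m_per_mm3: 1.69
    label_probs: {nuclear: 0.71, cytoplasmic: 0.0, both: 0.0, none: 0.29}
    shape:
      ellipsoid:
        semi_axes_um: [7040.0, 4300.0, 10741.066]
    design:
      section_period: 30
      cut_thickness_um: 50.0
      mounted_thickness_um: 20.0
      grid_um: [2000.0, 2000.0]
      frame_um: [150.0, 150.0]
      disector_height_um: 18.0
      guard_um: 1.0
      ball_radius_um: 18.0
      cavalieri_spacing_um: 2000.0
"""
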