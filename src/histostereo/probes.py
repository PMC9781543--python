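"""Design-based stereological probes.

Implements the estimators of the StereoInvestigator workflow used on the
dolphin auditory nuclei:

* Cavalieri volume estimation from systematically spaced sections with
  point counting, V = d · a_p · ΣP;
* the Gundersen–Jensen coefficient of error from the covariogram terms of
  the per-section counts;
* systematic random sampling (SRS) grid site placement;
* unbiased counting-frame / optical-disector counting and the optical
  fractionator, N = ΣQ⁻ · (1/ssf)(1/asf)(1/tsf);
* the Spaceballs length estimator from transversal fiber–sphere surface
  intersections, Lv = 2ΣI / (Σ probe area).

All geometry is in µm. Counting rules for point-like items use half-open
intervals on every axis, which is mathematically identical to the
inclusion/exclusion-line rule for points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .errors import ProbeError, UndefinedCEError
from .synthetic import SectionStack

__all__ = [
    "SamplingDesign",
    "SectionCounts",
    "Estimate",
    "place_srs_grid",
    "count_in_frame",
    "point_count_section",
    "cavalieri_volume",
    "gundersen_ce",
    "optical_fractionator",
    "spaceballs_length",
    "sphere_zone_area",
    "intersect_fiber_sphere",
    "run_probe",
]


@dataclass(frozen=True)
class SamplingDesign:
    """All probe parameters of one sampling design (lengths in µm).

    Defaults follow the inferior-colliculus neuron design: every 30th
    50 µm section, a 2000 × 2000 µm SRS grid, a 150 × 150 µm counting
    frame, an 18 µm optical disector with 1 µm guard zones in a 20 µm
    mounted section, and an 18 µm Spaceball radius.
    """

    section_period: int = 30
    cut_thickness_um: float = 50.0
    mounted_thickness_um: float = 20.0
    grid_um: tuple[float, float] = (2000.0, 2000.0)
    frame_um: tuple[float, float] = (150.0, 150.0)
    disector_height_um: float = 18.0
    guard_um: float = 1.0
    ball_radius_um: float = 18.0
    cavalieri_spacing_um: float = 2000.0

    def __post_init__(self):
        if self.section_period < 1:
            raise ProbeError("section_period must be >= 1")
        lengths = (
            self.cut_thickness_um,
            self.mounted_thickness_um,
            *self.grid_um,
            *self.frame_um,
            self.disector_height_um,
            self.ball_radius_um,
            self.cavalieri_spacing_um,
        )
        if any(v <= 0 for v in lengths):
            raise ProbeError("all design lengths must be positive")
        if self.guard_um < 0:
            raise ProbeError("guard zone must be >= 0")
        if self.disector_height_um + 2 * self.guard_um > self.mounted_thickness_um + 1e-9:
            raise ProbeError("disector height + guard zones must fit in the mounted thickness")
        if self.frame_um[0] > self.grid_um[0] or self.frame_um[1] > self.grid_um[1]:
            raise ProbeError("counting frame must fit inside one grid cell")

    # sampling fractions -------------------------------------------------
    @property
    def ssf(self) -> float:
        """Section sampling fraction 1/k."""
        return 1.0 / self.section_period

    @property
    def asf(self) -> float:
        """Area sampling fraction: frame area over grid-cell area."""
        return (self.frame_um[0] * self.frame_um[1]) / (self.grid_um[0] * self.grid_um[1])

    @property
    def tsf(self) -> float:
        """Thickness sampling fraction: disector height over mounted thickness."""
        return self.disector_height_um / self.mounted_thickness_um

    @property
    def inter_section_distance_um(self) -> float:
        return self.section_period * self.cut_thickness_um

    # presets ------------------------------------------------------------
    @classmethod
    def ic_neurons(cls) -> "SamplingDesign":
        return cls()

    @classmethod
    def ic_glia(cls) -> "SamplingDesign":
        return cls(frame_um=(30.0, 30.0))

    @classmethod
    def vcn_neurons(cls) -> "SamplingDesign":
        return cls(section_period=20, grid_um=(1000.0, 1000.0), cavalieri_spacing_um=1000.0)

    @classmethod
    def vcn_glia(cls) -> "SamplingDesign":
        return cls(
            section_period=20,
            grid_um=(1000.0, 1000.0),
            frame_um=(30.0, 30.0),
            cavalieri_spacing_um=1000.0,
        )


@dataclass
class SectionCounts:
    """Per-section probe tallies (P, Q⁻ or I depending on the probe)."""

    section_indices: list[int]
    tallies: np.ndarray
    sites_per_section: np.ndarray
    probe_kind: str = ""
    counted_items: pd.DataFrame | None = None

    def __post_init__(self):
        self.tallies = np.asarray(self.tallies, dtype=int)
        self.sites_per_section = np.asarray(self.sites_per_section, dtype=int)
        if (self.tallies < 0).any():
            raise ProbeError("tallies must be non-negative")

    @property
    def total(self) -> int:
        return int(self.tallies.sum())

    @property
    def n_sites(self) -> int:
        return int(self.sites_per_section.sum())


@dataclass
class Estimate:
    """A stereological estimate with its CE and its scaling provenance.

    ``components`` records every factor applied, so the value is always
    reproducible as the product of ``components`` values (times the raw
    total, which is itself one of the components).
    """

    value: float
    ce: float
    components: dict[str, float]
    units: str = ""
    kind: str = ""

    @property
    def ce_defined(self) -> bool:
        return not math.isnan(self.ce)

    def value_from_components(self) -> float:
        out = 1.0
        for v in self.components.values():
            out *= v
        return out


# ---------------------------------------------------------------------------
# SRS site placement and frame counting
# ---------------------------------------------------------------------------

def place_srs_grid(
    section_polygon: Polygon,
    grid_um: tuple[float, float],
    seed: int | np.random.Generator,
    frame_um: tuple[float, float] | None = None,
) -> np.ndarray:
    """Systematic random sampling site origins over a section contour.

    A single uniform random offset in [0, gx) × [0, gy) shifts a regular
    grid; the returned sites are the grid translates whose counting frame
    (``frame_um``, defaulting to the full grid cell) intersects the
    polygon. Deterministic per seed. A degenerate polygon yields no sites.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gx, gy = grid_um
    offset = rng.uniform((0.0, 0.0), (gx, gy))
    return _srs_sites(section_polygon, grid_um, tuple(offset), frame_um)


def _srs_sites(
    section_polygon: Polygon | None,
    grid_um: tuple[float, float],
    offset: tuple[float, float],
    frame_um: tuple[float, float] | None,
) -> np.ndarray:
    """Grid translates of a fixed offset whose frame intersects the polygon."""
    gx, gy = grid_um
    if section_polygon is None or section_polygon.is_empty or section_polygon.area == 0:
        return np.empty((0, 2), dtype=float)
    fw, fh = frame_um if frame_um is not None else (gx, gy)
    minx, miny, maxx, maxy = section_polygon.bounds
    i0 = math.floor((minx - offset[0] - fw) / gx)
    i1 = math.ceil((maxx - offset[0]) / gx)
    j0 = math.floor((miny - offset[1] - fh) / gy)
    j1 = math.ceil((maxy - offset[1]) / gy)
    sites = []
    shapely.prepare(section_polygon)
    for i in range(i0, i1 + 1):
        ox = offset[0] + i * gx
        for j in range(j0, j1 + 1):
            oy = offset[1] + j * gy
            if section_polygon.intersects(box(ox, oy, ox + fw, oy + fh)):
                sites.append((ox, oy))
    return np.asarray(sites, dtype=float).reshape(-1, 2)


def count_in_frame(
    points: pd.DataFrame | np.ndarray,
    frame_origin_um: tuple[float, float],
    frame_size_um: tuple[float, float],
    z_window_um: tuple[float, float],
) -> int:
    """Count points inside one unbiased counting frame / optical disector.

    Half-open on all axes: x ∈ [x₀, x₀+fw), y ∈ [y₀, y₀+fh),
    z ∈ [z_lo, z_hi). For point-like counting items this is equivalent to
    the inclusion/exclusion-line rule — a point on an exclusion (left or
    bottom) boundary belongs to the neighbouring frame.
    """
    if isinstance(points, pd.DataFrame):
        xyz = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    else:
        xyz = np.atleast_2d(np.asarray(points, dtype=float))
    if xyz.size == 0:
        return 0
    x0, y0 = frame_origin_um
    fw, fh = frame_size_um
    z_lo, z_hi = z_window_um
    m = (
        (xyz[:, 0] >= x0)
        & (xyz[:, 0] < x0 + fw)
        & (xyz[:, 1] >= y0)
        & (xyz[:, 1] < y0 + fh)
        & (xyz[:, 2] >= z_lo)
        & (xyz[:, 2] < z_hi)
    )
    return int(m.sum())


# ---------------------------------------------------------------------------
# Cavalieri
# ---------------------------------------------------------------------------

def point_count_section(
    section_polygon: Polygon | None,
    point_grid_spacing_um: float,
    seed: int | np.random.Generator,
) -> int:
    """Number of randomly offset square-grid points hitting the contour.

    E[P] = polygon area / spacing², the planimetric identity behind the
    Cavalieri point-counting probe.
    """
    if point_grid_spacing_um <= 0:
        raise ProbeError("point grid spacing must be positive")
    if section_polygon is None or section_polygon.is_empty or section_polygon.area == 0:
        return 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = point_grid_spacing_um
    off = rng.uniform((0.0, 0.0), (s, s))
    minx, miny, maxx, maxy = section_polygon.bounds
    xs = np.arange(off[0] + math.floor((minx - off[0]) / s) * s, maxx + s, s)
    ys = np.arange(off[1] + math.floor((miny - off[1]) / s) * s, maxy + s, s)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(section_polygon, gx.ravel(), gy.ravel())
    return int(inside.sum())


def gundersen_ce(
    counts: Sequence[int] | np.ndarray,
    smoothness_m: int = 1,
    nugget: bool = False,
) -> float:
    """Gundersen–Jensen coefficient of error of a systematic sample.

    Uses the covariogram terms A = Σcᵢ², B = Σcᵢcᵢ₊₁, C = Σcᵢcᵢ₊₂ of the
    ordered per-section counts. With smoothness class m=1 the systematic
    variance is (3(A−ν) − 4B + C)/240 (divisor 12 for m=0), where the
    nugget ν = Σcᵢ removes local point/Poisson noise from the covariogram
    and is added back as counting noise:

        CE = sqrt(Var_SRS + ν·[nugget]) / Σcᵢ.

    The nugget is conventional for disector counts (Poisson noise at each
    site); for Cavalieri point counts on smooth contours it is off by
    default.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.size < 1:
        raise UndefinedCEError("CE requires at least one section count")
    total = c.sum()
    if total <= 0:
        raise UndefinedCEError("CE undefined for an all-zero count sequence")
    if smoothness_m not in (0, 1):
        raise ProbeError("smoothness_m must be 0 or 1")
    A = float(np.dot(c, c))
    B = float(np.dot(c[:-1], c[1:])) if c.size > 1 else 0.0
    C = float(np.dot(c[:-2], c[2:])) if c.size > 2 else 0.0
    nu = total if nugget else 0.0
    if smoothness_m == 1:
        var_srs = (3.0 * (A - nu) - 4.0 * B + C) / 240.0
    else:
        var_srs = (3.0 * (A - nu) - 4.0 * B + C) / 12.0
    var = var_srs + (nu if nugget else 0.0)
    return math.sqrt(max(var, 0.0)) / total


def cavalieri_volume(
    section_point_counts: Sequence[int] | np.ndarray,
    inter_section_distance_um: float,
    area_per_point_um2: float,
    nugget: bool = False,
) -> Estimate:
    """Cavalieri volume: V = d · a_p · ΣP, CE from the Gundersen–Jensen form.

    ``d`` is the distance between sampled sections (period × cut thickness)
    and ``a_p`` the area associated with one grid point (spacing²).
    """
    counts = np.asarray(list(section_point_counts), dtype=int)
    if counts.size == 0:
        raise ProbeError("cavalieri_volume requires at least one section count")
    if inter_section_distance_um <= 0 or area_per_point_um2 <= 0:
        raise ProbeError("d and a_p must be positive")
    total = int(counts.sum())
    value = inter_section_distance_um * area_per_point_um2 * total
    try:
        ce = gundersen_ce(counts, smoothness_m=1, nugget=nugget)
    except UndefinedCEError:
        ce = float("nan")
    return Estimate(
        value=value,
        ce=ce,
        components={
            "sum_P": float(total),
            "d_um": inter_section_distance_um,
            "a_p_um2": area_per_point_um2,
        },
        units="um3",
        kind="cavalieri",
    )


# ---------------------------------------------------------------------------
# Optical fractionator
# ---------------------------------------------------------------------------

def optical_fractionator(
    section_Q_counts: Sequence[int] | np.ndarray | SectionCounts,
    design: SamplingDesign,
) -> Estimate:
    """Optical-fractionator total: N = ΣQ⁻ · (1/ssf)(1/asf)(1/tsf).

    CE via the Gundersen–Jensen m=1 form with the nugget on (disector
    counts carry Poisson noise). ΣQ = 0 gives value 0 with the CE flagged
    undefined (NaN).
    """
    if isinstance(section_Q_counts, SectionCounts):
        counts = section_Q_counts.tallies
    else:
        counts = np.asarray(list(section_Q_counts), dtype=int)
    if counts.size == 0:
        raise ProbeError("optical_fractionator requires at least one section count")
    total = int(counts.sum())
    value = total / (design.ssf * design.asf * design.tsf)
    try:
        ce = gundersen_ce(counts, smoothness_m=1, nugget=True)
    except UndefinedCEError:
        ce = float("nan")
    return Estimate(
        value=value,
        ce=ce,
        components={
            "sum_Q": float(total),
            "inv_ssf": 1.0 / design.ssf,
            "inv_asf": 1.0 / design.asf,
            "inv_tsf": 1.0 / design.tsf,
        },
        units="count",
        kind="fractionator",
    )


# ---------------------------------------------------------------------------
# Spaceballs
# ---------------------------------------------------------------------------

def sphere_zone_area(radius_um: float, slab_height_um: float) -> float:
    """Lateral area of a sphere truncated to a centred slab (Archimedes).

    The area of the spherical surface between two parallel planes a
    distance h apart is 2πr·h for h ≤ 2r, independently of where the slab
    sits; for h ≥ 2r it is the full sphere, 4πr².
    """
    if radius_um <= 0 or slab_height_um <= 0:
        raise ProbeError("radius and slab height must be positive")
    return 2.0 * math.pi * radius_um * min(slab_height_um, 2.0 * radius_um)


def spaceballs_length(
    section_I_counts: Sequence[int] | np.ndarray | SectionCounts,
    design: SamplingDesign,
    n_sites: int | None = None,
    reference_volume_um3: float | None = None,
    full_sphere: bool = False,
) -> Estimate:
    """Spaceballs length density and total length.

    Each site carries a sphere of radius r whose surface is restricted to
    the disector slab (a full 36 µm sphere cannot fit a 20 µm mounted
    section), giving probe area S = 2πr·min(h, 2r) per site
    (``full_sphere`` uses 4πr² for thick synthetic blocks). The unbiased
    length density is

        Lv = 2·ΣI / (n_sites · S)   [µm⁻²; ×10³ = m/mm³]

    and total length = Lv × reference volume when a reference volume is
    supplied.
    """
    if isinstance(section_I_counts, SectionCounts):
        counts = section_I_counts.tallies
        if n_sites is None:
            n_sites = section_I_counts.n_sites
    else:
        counts = np.asarray(list(section_I_counts), dtype=int)
    if n_sites is None or n_sites <= 0:
        raise ProbeError("spaceballs_length requires a positive number of sites")
    r = design.ball_radius_um
    S = 4.0 * math.pi * r * r if full_sphere else sphere_zone_area(r, design.disector_height_um)
    total_I = int(np.asarray(counts).sum())
    lv_um2 = 2.0 * total_I / (n_sites * S)
    try:
        ce = gundersen_ce(counts, smoothness_m=1, nugget=True)
    except UndefinedCEError:
        ce = float("nan")
    components = {
        "sum_I": float(total_I),
        "two_over_site_area": 2.0 / (n_sites * S),
    }
    if reference_volume_um3 is not None:
        if reference_volume_um3 <= 0:
            raise ProbeError("reference volume must be positive")
        components["reference_volume_um3"] = reference_volume_um3
        value = lv_um2 * reference_volume_um3
        units = "um"
    else:
        value = lv_um2
        units = "per_um2"
    return Estimate(value=value, ce=ce, components=components, units=units, kind="spaceballs")


def intersect_fiber_sphere(
    segment: np.ndarray,
    sphere_center_um: np.ndarray,
    radius_um: float,
    slab_um: tuple[float, float] | None = None,
) -> int:
    """Transversal crossings of one segment with a (slab-restricted) sphere surface.

    Solves |a + t·(b−a) − c|² = r² for t ∈ [0, 1] and keeps roots whose z
    lies in the slab. Tangencies (zero discriminant) count 0.
    """
    seg = np.asarray(segment, dtype=float).reshape(6)
    return int(
        _count_crossings(
            seg[None, :], np.asarray(sphere_center_um, dtype=float), radius_um, slab_um
        )[0]
    )


def _count_crossings(
    segs: np.ndarray,
    center: np.ndarray,
    r: float,
    slab: tuple[float, float] | None,
) -> np.ndarray:
    """Vectorized crossing counts for an array of segments, one sphere."""
    a = segs[:, :3] - center
    d = segs[:, 3:] - segs[:, :3]
    qa = np.einsum("ij,ij->i", d, d)
    qb = 2.0 * np.einsum("ij,ij->i", a, d)
    qc = np.einsum("ij,ij->i", a, a) - r * r
    disc = qb * qb - 4.0 * qa * qc
    ok = (disc > 0) & (qa > 0)
    counts = np.zeros(len(segs), dtype=int)
    if not ok.any():
        return counts
    sq = np.sqrt(disc[ok])
    qa_ok, qb_ok = qa[ok], qb[ok]
    z0 = segs[ok, 2]
    dz = d[ok, 2]
    sub = np.zeros(ok.sum(), dtype=int)
    for sign in (-1.0, 1.0):
        t = (-qb_ok + sign * sq) / (2.0 * qa_ok)
        valid = (t >= 0.0) & (t <= 1.0)
        if slab is not None:
            z = z0 + t * dz
            valid &= (z >= slab[0]) & (z <= slab[1])
        sub += valid.astype(int)
    counts[ok] = sub
    return counts


# ---------------------------------------------------------------------------
# Probe runner
# ---------------------------------------------------------------------------

def _make_filter(item_filter) -> Callable[[pd.DataFrame], pd.DataFrame]:
    if item_filter is None:
        return lambda df: df
    if callable(item_filter):
        return item_filter

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        m = np.ones(len(df), dtype=bool)
        for col, wanted in item_filter.items():
            vals = (wanted,) if isinstance(wanted, str) else tuple(wanted)
            m &= df[col].isin(vals).to_numpy()
        return df.loc[m]

    return _apply


def run_probe(
    stack: SectionStack,
    design: SamplingDesign,
    item_filter: Mapping[str, object] | Callable | None = None,
    probe_kind: str = "fractionator",
    seed: int | None = None,
    first_section: int | None = None,
) -> SectionCounts:
    """Run a sampling probe over every k-th section of a stack.

    Selects sections ``first_section, first_section + k, ...`` (the offset
    uniform in [0, k) when not given), places an SRS site grid on each
    sampled section's contour, and applies the probe at every site:

    * ``fractionator``: disector counts Q⁻ of filtered points per frame;
    * ``spaceballs``: transversal fiber crossings I with the slab-restricted
      sphere surface centred at each site;
    * ``cavalieri``: grid-point hits P on the section contour.

    A site whose frame partly leaves the contour still counts the items
    inside its frame (no border correction beyond the frame rule).
    """
    if stack.n_sections == 0:
        raise ProbeError("cannot probe an empty stack")
    if probe_kind not in ("fractionator", "spaceballs", "cavalieri"):
        raise ProbeError(f"unknown probe kind {probe_kind!r}")
    if probe_kind == "fractionator" and abs(
        stack.mounted_thickness_um - design.mounted_thickness_um
    ) > 1e-6:
        raise ProbeError(
            f"design mounted thickness {design.mounted_thickness_um} µm does not match "
            f"the stack's {stack.mounted_thickness_um} µm; the thickness sampling "
            "fraction would be wrong"
        )
    rng = np.random.default_rng(seed)
    k = design.section_period
    start = int(rng.integers(k)) if first_section is None else int(first_section)
    sampled = list(range(start, stack.n_sections, k))
    if not sampled:
        return SectionCounts([], np.zeros(0), np.zeros(0), probe_kind=probe_kind)

    flt = _make_filter(item_filter)
    tallies: list[int] = []
    sites_n: list[int] = []
    counted_frames: list[pd.DataFrame] = []
    t_m = stack.mounted_thickness_um
    z_lo = design.guard_um
    z_hi = design.guard_um + design.disector_height_um

    for i in sampled:
        poly = stack.section_polygon(i)
        if probe_kind == "cavalieri":
            tallies.append(point_count_section(poly, design.cavalieri_spacing_um, rng))
            sites_n.append(1)
            continue
        if probe_kind == "fractionator":
            # the lattice offset alone defines the frames; the polygon is only
            # needed to enumerate sites, so a missing pole-cap contour cannot
            # drop counts
            offset = tuple(rng.uniform((0.0, 0.0), design.grid_um))
            sites = _srs_sites(poly, design.grid_um, offset, design.frame_um)
            pts = flt(stack.section_points(i))
            q, kept = _count_fractionator_section(pts, offset, design, (z_lo, z_hi))
            tallies.append(q)
            sites_n.append(len(sites))
            if kept is not None and len(kept):
                kept = kept.copy()
                kept["section_index"] = i
                counted_frames.append(kept)
        else:  # spaceballs
            if poly is None:
                raise ProbeError(
                    "spaceballs requires section contours (build the stack from a region)"
                )
            sites = place_srs_grid(poly, design.grid_um, rng, frame_um=None)
            # keep sites whose centre lies in the tissue
            if len(sites):
                inside = shapely.contains_xy(poly, sites[:, 0], sites[:, 1])
                sites = sites[inside]
            segs = stack.section_fibers(i)
            slab = (z_lo, z_hi)
            z_c = 0.5 * (z_lo + z_hi)
            count = 0
            if len(segs) and len(sites):
                count = _spaceballs_section(segs, sites, z_c, design.ball_radius_um, slab)
            tallies.append(count)
            sites_n.append(len(sites))

    counted = pd.concat(counted_frames, ignore_index=True) if counted_frames else None
    return SectionCounts(
        section_indices=sampled,
        tallies=np.asarray(tallies, dtype=int),
        sites_per_section=np.asarray(sites_n, dtype=int),
        probe_kind=probe_kind,
        counted_items=counted,
    )


def _count_fractionator_section(
    pts: pd.DataFrame,
    lattice_offset: tuple[float, float],
    design: SamplingDesign,
    z_window: tuple[float, float],
) -> tuple[int, pd.DataFrame | None]:
    """Vectorized disector counting over all SRS sites of one section.

    Every point inside tissue lies in exactly one grid translate, and that
    translate's frame is always a valid site (it intersects the tissue at
    the point itself), so per-point lattice-membership tests are equivalent
    to looping ``count_in_frame`` over the enumerated sites.
    """
    if len(pts) == 0:
        return 0, None
    xyz = pts[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    gx, gy = design.grid_um
    fw, fh = design.frame_um
    zm = (xyz[:, 2] >= z_window[0]) & (xyz[:, 2] < z_window[1])
    dx = np.mod(xyz[:, 0] - lattice_offset[0], gx)
    dy = np.mod(xyz[:, 1] - lattice_offset[1], gy)
    in_frame = (dx < fw) & (dy < fh) & zm
    return int(in_frame.sum()), pts.loc[in_frame]


def _spaceballs_section(
    segs: np.ndarray,
    sites: np.ndarray,
    z_center: float,
    r: float,
    slab: tuple[float, float],
) -> int:
    """Sum transversal crossings over all sites of one section."""
    mid = 0.5 * (segs[:, :3] + segs[:, 3:])
    half = 0.5 * np.linalg.norm(segs[:, 3:] - segs[:, :3], axis=1)
    reach = half + r
    order = np.argsort(mid[:, 0])
    xs = mid[order, 0]
    max_reach = float(reach.max()) if len(reach) else 0.0
    total = 0
    for sx, sy in sites:
        lo = np.searchsorted(xs, sx - r - max_reach)
        hi = np.searchsorted(xs, sx + r + max_reach)
        cand = order[lo:hi]
        if not len(cand):
            continue
        near = np.abs(mid[cand, 1] - sy) <= reach[cand]
        cand = cand[near]
        if not len(cand):
            continue
        center = np.array([sx, sy, z_center])
        total += int(_count_crossings(segs[cand], center, r, slab).sum())
    return total
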