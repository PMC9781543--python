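"""Synthetic tissue: cell and fiber fields with known ground truth, and the
serial-sectioning model that turns them into mounted histological sections.

The simulator emulates how the dolphin auditory nuclei were processed:
homogeneous Poisson neuron/glia fields at stated densities, Bernoulli
immunoreactivity-compartment labels, isotropic fiber (axon) fields at stated
length densities, coronal cutting into 50 µm sections along z, z-collapse of
each mounted section to its mounted thickness, linear xy shrinkage, and
optional truncation of the caudal end of the stack.

Point containers are pandas DataFrames with columns
``x_um, y_um, z_um, cell_class, marker, compartment``; fiber containers are
float arrays of shape (n, 6) holding segment endpoints
``x0, y0, z0, x1, y1, z1`` in µm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely import affinity
from shapely.geometry import Polygon

from .errors import GeometryError, SimulationError
from .regions import EllipsoidGeometry, Region

__all__ = [
    "CELL_CLASSES",
    "MARKERS",
    "COMPARTMENTS",
    "POINT_COLUMNS",
    "ShrinkageModel",
    "Section",
    "SectionStack",
    "simulate_neuron_field",
    "simulate_glia_field",
    "simulate_fiber_field",
    "section_stack",
    "fiber_lengths",
    "total_length",
]

CELL_CLASSES = ("neuron", "astrocyte", "microglia")
MARKERS = ("Abeta", "FN", "TDP43", "pNFP", "Iba1", "GFAP")
COMPARTMENTS = ("nuclear", "cytoplasmic", "both", "none")
POINT_COLUMNS = ("x_um", "y_um", "z_um", "cell_class", "marker", "compartment")

#: compartments a glial cell may carry (no nuclear-only / both patterns)
GLIA_COMPARTMENTS = ("cytoplasmic", "none")


@dataclass(frozen=True)
class ShrinkageModel:
    """Histological processing distortion.

    ``xy_linear_factor``: linear in-plane shrinkage, in (0, 1]; areas scale
    by its square. ``z_collapse_factor``: mounted thickness / cut thickness,
    in (0, 1] — sections dry down on the slide. ``truncation_fraction``:
    fraction of sections removed from the caudal end of the stack, in [0, 1).
    """

    xy_linear_factor: float = 1.0
    z_collapse_factor: float = 1.0
    truncation_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.xy_linear_factor <= 1.0):
            raise SimulationError("xy_linear_factor must be in (0, 1]")
        if not (0.0 < self.z_collapse_factor <= 1.0):
            raise SimulationError("z_collapse_factor must be in (0, 1]")
        if not (0.0 <= self.truncation_fraction < 1.0):
            raise SimulationError("truncation_fraction must be in [0, 1)")

    @classmethod
    def identity(cls) -> "ShrinkageModel":
        return cls(1.0, 1.0, 0.0)


def _empty_points() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "z_um": pd.Series(dtype=float),
            "cell_class": pd.Series(dtype=object),
            "marker": pd.Series(dtype=object),
            "compartment": pd.Series(dtype=object),
        }
    )


def _validate_label_probs(label_probs: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    if isinstance(label_probs, Mapping):
        unknown = set(label_probs) - set(COMPARTMENTS)
        if unknown:
            raise SimulationError(f"unknown compartment labels: {sorted(unknown)}")
        p = np.array([float(label_probs.get(c, 0.0)) for c in COMPARTMENTS])
    else:
        p = np.asarray(list(label_probs), dtype=float)
        if p.shape != (4,):
            raise SimulationError("label_probs must give 4 probabilities (nuclear, cytoplasmic, both, none)")
    if (p < 0).any():
        raise SimulationError("label probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise SimulationError(f"label probabilities must sum to 1, got {p.sum()!r}")
    return p


def simulate_neuron_field(
    region: Region,
    density_per_mm3: float,
    label_probs: Mapping[str, float] | Sequence[float],
    seed: int,
    marker: str = "Abeta",
    min_distance_um: float | None = None,
) -> pd.DataFrame:
    """Homogeneous Poisson neuron field with i.i.d. compartment labels.

    The expected count is ``density_per_mm3 × region volume``; positions are
    uniform in the region; each neuron's immunoreactivity compartment is an
    independent draw from ``label_probs`` over
    (nuclear, cytoplasmic, both, none). Deterministic for a given seed.

    ``min_distance_um`` switches on a simple hard-core (dart-throwing)
    thinning; it is off by default because the estimators' unbiasedness
    derivations assume no point interaction.
    """
    if density_per_mm3 < 0:
        raise SimulationError("density must be non-negative")
    p = _validate_label_probs(label_probs)
    rng = np.random.default_rng(seed)
    lam = density_per_mm3 / 1e9  # per µm³
    n = rng.poisson(lam * region.true_volume_um3)
    if n == 0:
        return _empty_points()
    xyz = region.sample_uniform(n, rng)
    if min_distance_um:
        xyz = _hard_core_thin(xyz, min_distance_um)
        n = len(xyz)
    comp = rng.choice(np.array(COMPARTMENTS, dtype=object), size=n, p=p)
    return pd.DataFrame(
        {
            "x_um": xyz[:, 0],
            "y_um": xyz[:, 1],
            "z_um": xyz[:, 2],
            "cell_class": np.full(n, "neuron", dtype=object),
            "marker": np.full(n, marker, dtype=object),
            "compartment": comp,
        }
    )


def _hard_core_thin(xyz: np.ndarray, min_distance: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    keep: list[int] = []
    tree = cKDTree(xyz)
    killed = np.zeros(len(xyz), dtype=bool)
    for i in range(len(xyz)):
        if killed[i]:
            continue
        keep.append(i)
        for j in tree.query_ball_point(xyz[i], min_distance):
            if j > i:
                killed[j] = True
    return xyz[keep]


def simulate_glia_field(
    region: Region,
    density_per_mm3: float,
    cell_class: str,
    seed: int,
    marker: str | None = None,
) -> pd.DataFrame:
    """Poisson glial field; compartment fixed to cytoplasmic.

    Glial immunoreactivity was scored as cytoplasmic only (Iba-1 microglia,
    GFAP astrocytes), so no nuclear/both patterns are generated.
    """
    if cell_class not in ("astrocyte", "microglia"):
        raise SimulationError(f"cell_class must be 'astrocyte' or 'microglia', got {cell_class!r}")
    if marker is None:
        marker = "GFAP" if cell_class == "astrocyte" else "Iba1"
    pts = simulate_neuron_field(
        region, density_per_mm3, {"cytoplasmic": 1.0}, seed, marker=marker
    )
    pts["cell_class"] = np.full(len(pts), cell_class, dtype=object)
    return pts


def simulate_fiber_field(
    region: Region,
    length_density_m_per_mm3: float,
    mean_segment_length_um: float = 500.0,
    seed: int = 0,
) -> np.ndarray:
    """Isotropic line-segment (axon) field at a prescribed length density.

    Segment midpoints form a Poisson process in the region dilated by one
    segment length (so fibers crossing the boundary are represented without
    edge bias); orientations are uniform on the sphere; each generated
    segment is clipped to the region and only the in-region chord is kept.
    By stationarity the expected retained length is exactly
    ``length density × region volume``.

    Only convex (ellipsoid) regions are supported: the in-region part of a
    chord is then a single interval found by one quadratic solve.
    """
    if length_density_m_per_mm3 < 0:
        raise SimulationError("length density must be non-negative")
    if mean_segment_length_um <= 0:
        raise SimulationError("mean segment length must be positive")
    if length_density_m_per_mm3 == 0:
        return np.empty((0, 6), dtype=float)
    geom = region.geometry
    if not isinstance(geom, EllipsoidGeometry):
        raise GeometryError("fiber fields require an ellipsoid region")

    rng = np.random.default_rng(seed)
    L = mean_segment_length_um
    lv_um2 = length_density_m_per_mm3 / 1e3  # µm / µm³
    dil = geom.dilated(L)
    lam = lv_um2 / L  # midpoints per µm³
    n = rng.poisson(lam * dil.volume_um3)
    if n == 0:
        return np.empty((0, 6), dtype=float)

    dil_region = Region(region.name, dil)
    mid = dil_region.sample_uniform(n, rng)
    # isotropic directions: uniform cos(theta), uniform phi
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    a = mid - 0.5 * L * u
    b = mid + 0.5 * L * u
    return clip_segments_to_ellipsoid(a, b, geom)


def clip_segments_to_ellipsoid(
    a: np.ndarray, b: np.ndarray, geom: EllipsoidGeometry
) -> np.ndarray:
    """Clip segments A→B to an ellipsoid; returns the inside chords, (m, 6).

    Segments with both endpoints inside are kept whole without solving the
    quadratic (the ellipsoid is convex); at realistic field scales that is
    the vast majority, so only the boundary shell pays for root finding.
    """
    inside_a = geom.contains(a)
    inside_b = geom.contains(b)
    whole = inside_a & inside_b
    rest = ~whole
    out_whole = np.concatenate([a[whole], b[whole]], axis=1)
    if not rest.any():
        return out_whole

    ar, br = a[rest], b[rest]
    ax = np.asarray(geom.semi_axes)
    c = np.asarray(geom.center)
    A = (ar - c) / ax
    D = (br - ar) / ax
    qa = np.einsum("ij,ij->i", D, D)
    qb = 2.0 * np.einsum("ij,ij->i", A, D)
    qc = np.einsum("ij,ij->i", A, A) - 1.0
    disc = qb * qb - 4.0 * qa * qc
    valid = (disc > 0) & (qa > 0)
    sq = np.sqrt(np.where(valid, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r0 = (-qb - sq) / (2.0 * qa)
        r1 = (-qb + sq) / (2.0 * qa)
    t0 = np.clip(r0, 0.0, 1.0)
    t1 = np.clip(r1, 0.0, 1.0)
    keep = valid & (t1 > t0)
    if not keep.any():
        return out_whole
    ar, d = ar[keep], (br - ar)[keep]
    t0, t1 = t0[keep][:, None], t1[keep][:, None]
    out_clip = np.concatenate([ar + t0 * d, ar + t1 * d], axis=1)
    return np.concatenate([out_whole, out_clip], axis=0)


def fiber_lengths(segments: np.ndarray) -> np.ndarray:
    segments = np.asarray(segments, dtype=float).reshape(-1, 6)
    return np.linalg.norm(segments[:, 3:] - segments[:, :3], axis=1)


def total_length(segments: np.ndarray) -> float:
    return float(fiber_lengths(segments).sum())


@dataclass
class Section:
    """One mounted section in section-local coordinates.

    Local z runs over [0, mounted_thickness); xy coordinates are already
    shrunk by the xy linear factor. ``polygon`` is the (shrunk) tissue
    contour of this section, when the stack was built from a region.
    """

    index: int
    cut_thickness_um: float
    mounted_thickness_um: float
    z0_um: float  # global z of the rostral face, pre-shrinkage
    points: pd.DataFrame
    fibers: np.ndarray
    polygon: Polygon | None = None


class SectionStack:
    """An ordered stack of serial sections cut along z (rostral → caudal).

    Points are assigned to sections by half-open z intervals
    ``[z0 + i·t, z0 + (i+1)·t)`` so no point is assigned twice; fibers are
    cut at section faces and each section keeps its sub-chords. Within each
    mounted section, local z is rescaled by the z-collapse factor and xy by
    the linear shrinkage factor. Truncation removes ``⌈f·n⌉`` sections from
    the caudal (high-index) end.

    Fiber assignment is evaluated lazily per section: probe runs touch only
    every k-th section, so clipping the whole field eagerly would be wasted
    work at realistic field sizes.
    """

    def __init__(
        self,
        points: pd.DataFrame | None,
        fibers: np.ndarray | None,
        cut_thickness_um: float,
        shrinkage: ShrinkageModel,
        region: Region | None = None,
        z_range_um: tuple[float, float] | None = None,
    ):
        if cut_thickness_um <= 0:
            raise SimulationError("cut thickness must be positive")
        self.points_global = points if points is not None else _empty_points()
        self.fibers_global = (
            np.asarray(fibers, dtype=float).reshape(-1, 6)
            if fibers is not None
            else np.empty((0, 6), dtype=float)
        )
        self.cut_thickness_um = float(cut_thickness_um)
        self.shrinkage = shrinkage
        self.region = region

        if z_range_um is not None:
            z_lo, z_hi = map(float, z_range_um)
        elif region is not None:
            lo, hi = region.bounds
            z_lo, z_hi = float(lo[2]), float(hi[2])
        else:
            zs = [self.points_global["z_um"].to_numpy()] if len(self.points_global) else []
            if len(self.fibers_global):
                zs.append(self.fibers_global[:, [2, 5]].ravel())
            if not zs:
                z_lo, z_hi = 0.0, cut_thickness_um
            else:
                allz = np.concatenate(zs)
                z_lo, z_hi = float(allz.min()), float(allz.max()) + 1e-9
        self.z0_um = z_lo
        n_total = max(int(math.ceil((z_hi - z_lo) / cut_thickness_um)), 1)
        n_cut = int(math.ceil(shrinkage.truncation_fraction * n_total))
        self.n_sections_before_truncation = n_total
        self.n_sections = n_total - n_cut

        # eager point assignment (cheap, vectorized)
        z = self.points_global["z_um"].to_numpy()
        idx = np.floor((z - z_lo) / cut_thickness_um).astype(int)
        keep = (idx >= 0) & (idx < self.n_sections)
        self._point_section = idx
        self._point_keep = keep
        self._fiber_cache: dict[int, np.ndarray] = {}
        if len(self.fibers_global):
            zmin = np.minimum(self.fibers_global[:, 2], self.fibers_global[:, 5])
            zmax = np.maximum(self.fibers_global[:, 2], self.fibers_global[:, 5])
            self._fiber_order = np.argsort(zmin)
            self._fiber_zmin_sorted = zmin[self._fiber_order]
            self._fiber_zmax = zmax

    @property
    def mounted_thickness_um(self) -> float:
        return self.cut_thickness_um * self.shrinkage.z_collapse_factor

    def section_z0(self, i: int) -> float:
        return self.z0_um + i * self.cut_thickness_um

    def _check_index(self, i: int):
        if not (0 <= i < self.n_sections):
            raise IndexError(f"section {i} out of range [0, {self.n_sections})")

    def section_points(self, i: int) -> pd.DataFrame:
        """Points of section i in local (shrunk/mounted) coordinates."""
        self._check_index(i)
        s = self.shrinkage
        sel = self._point_keep & (self._point_section == i)
        sub = self.points_global.loc[sel].copy()
        sub["x_um"] = sub["x_um"].to_numpy() * s.xy_linear_factor
        sub["y_um"] = sub["y_um"].to_numpy() * s.xy_linear_factor
        sub["z_um"] = (sub["z_um"].to_numpy() - self.section_z0(i)) * s.z_collapse_factor
        return sub.reset_index(drop=True)

    def section_fibers(self, i: int) -> np.ndarray:
        """Fiber sub-chords of section i in local coordinates, (m, 6)."""
        self._check_index(i)
        if not len(self.fibers_global):
            return np.empty((0, 6), dtype=float)
        if i in self._fiber_cache:
            return self._fiber_cache[i]
        z_lo = self.section_z0(i)
        z_hi = z_lo + self.cut_thickness_um
        hi = np.searchsorted(self._fiber_zmin_sorted, z_hi, side="left")
        cand = self._fiber_order[:hi]
        cand = cand[self._fiber_zmax[cand] > z_lo]
        segs = self.fibers_global[cand]
        out = _clip_segments_to_slab(segs, z_lo, z_hi)
        s = self.shrinkage
        out[:, [0, 1, 3, 4]] *= s.xy_linear_factor
        out[:, [2, 5]] = (out[:, [2, 5]] - z_lo) * s.z_collapse_factor
        self._fiber_cache[i] = out
        return out

    def section_polygon(self, i: int) -> Polygon | None:
        """Tissue contour of section i (at its mid-height), xy-shrunk."""
        self._check_index(i)
        if self.region is None:
            return None
        z_mid = self.section_z0(i) + 0.5 * self.cut_thickness_um
        poly = self.region.section_polygon(z_mid)
        if poly is None:
            return None
        f = self.shrinkage.xy_linear_factor
        if f != 1.0:
            poly = affinity.scale(poly, xfact=f, yfact=f, origin=(0, 0))
        return poly

    def section(self, i: int) -> Section:
        return Section(
            index=i,
            cut_thickness_um=self.cut_thickness_um,
            mounted_thickness_um=self.mounted_thickness_um,
            z0_um=self.section_z0(i),
            points=self.section_points(i),
            fibers=self.section_fibers(i),
            polygon=self.section_polygon(i),
        )

    def point_counts(self) -> np.ndarray:
        """Per-section point tallies (length n_sections)."""
        counts = np.zeros(self.n_sections, dtype=int)
        sel = self._point_section[self._point_keep]
        if len(sel):
            np.add.at(counts, sel, 1)
        return counts


def _clip_segments_to_slab(segs: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
    """Clip segments to the half-open slab [z_lo, z_hi) along global z."""
    if not len(segs):
        return np.empty((0, 6), dtype=float)
    a = segs[:, :3].copy()
    b = segs[:, 3:].copy()
    dz = b[:, 2] - a[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = np.where(dz != 0, (z_lo - a[:, 2]) / dz, -np.inf)
        t_hi = np.where(dz != 0, (z_hi - a[:, 2]) / dz, np.inf)
    t0 = np.clip(np.minimum(t_lo, t_hi), 0.0, 1.0)
    t1 = np.clip(np.maximum(t_lo, t_hi), 0.0, 1.0)
    horizontal = dz == 0
    inside_h = horizontal & (a[:, 2] >= z_lo) & (a[:, 2] < z_hi)
    t0 = np.where(horizontal, np.where(inside_h, 0.0, 0.0), t0)
    t1 = np.where(horizontal, np.where(inside_h, 1.0, 0.0), t1)
    keep = t1 > t0
    a, b, t0, t1 = a[keep], b[keep], t0[keep][:, None], t1[keep][:, None]
    d = b - a
    return np.concatenate([a + t0 * d, a + t1 * d], axis=1)


def section_stack(
    region_content,
    cut_thickness_um: float,
    shrinkage: ShrinkageModel | None = None,
    region: Region | None = None,
    z_range_um: tuple[float, float] | None = None,
) -> SectionStack:
    """Cut simulated content into serial sections.

    ``region_content`` may be a points DataFrame, a fiber array (n, 6), or a
    tuple ``(points, fibers)``. Sections are indexed 0-based rostral→caudal
    with half-open z intervals, so with no truncation every point lands in
    exactly one section.
    """
    shrinkage = shrinkage or ShrinkageModel.identity()
    points: pd.DataFrame | None = None
    fibers: np.ndarray | None = None
    if isinstance(region_content, tuple):
        points, fibers = region_content
    elif isinstance(region_content, pd.DataFrame):
        points = region_content
    elif region_content is None:
        pass
    else:
        fibers = np.asarray(region_content, dtype=float)
    return SectionStack(
        points=points,
        fibers=fibers,
        cut_thickness_um=cut_thickness_um,
        shrinkage=shrinkage,
        region=region,
        z_range_um=z_range_um,
    )
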