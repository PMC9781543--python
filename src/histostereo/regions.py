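"""Region geometry: 3D nucleus shapes with known true volume.

A :class:`Region` represents one anatomical subnucleus (e.g. the central
nucleus of the inferior colliculus) as either an analytic ellipsoid or a
voxel mask, in µm, with the cutting axis along z (rostral → caudal).
Because the volume is known by construction, every downstream estimator can
be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .errors import GeometryError

__all__ = ["Region", "EllipsoidGeometry", "VoxelMaskGeometry", "make_region"]


@dataclass(frozen=True)
class EllipsoidGeometry:
    """Axis-aligned ellipsoid: semi-axes (a, b, c) in µm, centred at ``center``."""

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.semi_axes):
            raise GeometryError(f"semi-axes must be positive, got {self.semi_axes}")

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        ax = np.asarray(self.semi_axes, dtype=float)
        c = np.asarray(self.center, dtype=float)
        return c - ax, c + ax

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        # column-wise to avoid large (n, 3) temporaries at field scale
        r2 = np.zeros(len(xyz))
        for k in range(3):
            u = (xyz[:, k] - self.center[k]) / self.semi_axes[k]
            r2 += u * u
        return r2 <= 1.0

    def section_polygon(self, z: float, n_vertices: int = 128) -> Polygon | None:
        """Elliptic cross-section at height z, or None outside the body."""
        a, b, c = self.semi_axes
        cz = self.center[2]
        t = (z - cz) / c
        if abs(t) >= 1.0:
            return None
        scale = np.sqrt(1.0 - t * t)
        theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        xs = self.center[0] + a * scale * np.cos(theta)
        ys = self.center[1] + b * scale * np.sin(theta)
        return Polygon(np.column_stack([xs, ys]))

    def dilated(self, margin_um: float) -> "EllipsoidGeometry":
        """Enclosing ellipsoid grown by ``margin_um`` on every semi-axis.

        A superset of the true Minkowski dilation, which is all the fiber
        generator needs (midpoints outside it cannot reach the region).
        """
        a, b, c = self.semi_axes
        return EllipsoidGeometry((a + margin_um, b + margin_um, c + margin_um), self.center)


@dataclass(frozen=True)
class VoxelMaskGeometry:
    """Boolean occupancy grid with cubic voxels of edge ``voxel_size_um``."""

    mask: np.ndarray  # (nx, ny, nz) bool
    voxel_size_um: float
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3 or not m.any():
            raise GeometryError("voxel mask must be a non-empty 3D boolean array")
        if self.voxel_size_um <= 0:
            raise GeometryError("voxel size must be positive")
        object.__setattr__(self, "mask", m)

    @property
    def volume_um3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size_um**3

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        o = np.asarray(self.origin_um, dtype=float)
        hi = o + np.array(self.mask.shape, dtype=float) * self.voxel_size_um
        return o, hi

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        idx = np.floor((xyz - np.asarray(self.origin_um)) / self.voxel_size_um).astype(int)
        shape = np.array(self.mask.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(xyz), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def section_polygon(self, z: float, n_vertices: int = 0) -> Polygon | None:
        iz = int(np.floor((z - self.origin_um[2]) / self.voxel_size_um))
        if not (0 <= iz < self.mask.shape[2]):
            return None
        layer = self.mask[:, :, iz]
        if not layer.any():
            return None
        v = self.voxel_size_um
        ox, oy = self.origin_um[0], self.origin_um[1]
        boxes = [
            box(ox + i * v, oy + j * v, ox + (i + 1) * v, oy + (j + 1) * v)
            for i, j in zip(*np.nonzero(layer))
        ]
        merged = unary_union(boxes)
        if merged.geom_type == "MultiPolygon":
            merged = max(merged.geoms, key=lambda g: g.area)
        return merged


@dataclass(frozen=True)
class Region:
    """A named subnucleus with geometry and construction-known true volume."""

    name: str
    geometry: EllipsoidGeometry | VoxelMaskGeometry

    @property
    def true_volume_um3(self) -> float:
        return self.geometry.volume_um3

    @property
    def true_volume_mm3(self) -> float:
        return self.geometry.volume_um3 / 1e9

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.geometry.bounds

    @property
    def z_extent_um(self) -> float:
        lo, hi = self.geometry.bounds
        return float(hi[2] - lo[2])

    def contains(self, xyz: np.ndarray) -> np.ndarray:
        return self.geometry.contains(xyz)

    def section_polygon(self, z: float) -> Polygon | None:
        return self.geometry.section_polygon(z)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the region (rejection from bbox)."""
        lo, hi = self.geometry.bounds
        accept = self.geometry.volume_um3 / float(np.prod(hi - lo))
        parts: list[np.ndarray] = []
        have = 0
        while have < n:
            m = int((n - have) / max(accept, 0.05) * 1.1) + 64
            cand = rng.uniform(lo, hi, size=(m, 3))
            good = cand[self.geometry.contains(cand)]
            parts.append(good)
            have += len(good)
        return np.concatenate(parts)[:n] if len(parts) > 1 else parts[0][:n]


def make_region(name: str, shape_spec: dict) -> Region:
    """Build a Region from a shape specification.

    ``shape_spec`` is one of::

        {"ellipsoid": {"semi_axes_um": [a, b, c], "center_um": [x, y, z]}}
        {"voxel_mask": {"mask": <3D bool array>, "voxel_size_um": v,
                        "origin_um": [x, y, z]}}

    The true volume is 4/3·π·abc for ellipsoids, voxel count × voxel volume
    for masks.
    """
    if "ellipsoid" in shape_spec:
        e = shape_spec["ellipsoid"]
        geom = EllipsoidGeometry(
            tuple(float(s) for s in e["semi_axes_um"]),
            tuple(float(s) for s in e.get("center_um", (0.0, 0.0, 0.0))),
        )
    elif "voxel_mask" in shape_spec:
        m = shape_spec["voxel_mask"]
        geom = VoxelMaskGeometry(
            np.asarray(m["mask"], dtype=bool),
            float(m["voxel_size_um"]),
            tuple(float(s) for s in m.get("origin_um", (0.0, 0.0, 0.0))),
        )
    else:
        raise GeometryError(
            f"shape_spec must contain 'ellipsoid' or 'voxel_mask', got {sorted(shape_spec)}"
        )
    return Region(name=name, geometry=geom)
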