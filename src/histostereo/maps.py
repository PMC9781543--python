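"""Marker distribution maps: coronal-plane projections of 3D marker
coordinates rendered as smoothed density heatmaps inside averaged region
contours.

All counted cells (or fiber intersection points) are pooled across
sections and projected onto the x–y (coronal) plane; the per-section
region contours are averaged into a single representative outline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .errors import HistostereoError

__all__ = ["HeatmapGrid", "average_contour", "marker_heatmap"]


@dataclass
class HeatmapGrid:
    """A smoothed, max-normalized 2D marker-density grid.

    ``intensity`` has max 1 (or is all zero); ``mass`` is the unnormalized
    smoothed grid whose sum equals the number of input points (the Gaussian
    kernel is normalized and the boundary reflecting, so no mass is lost).
    """

    intensity: np.ndarray
    mass: np.ndarray
    pixel_size_um: float
    x0_um: float
    y0_um: float
    contours: list = field(default_factory=list)
    point_overlays: dict = field(default_factory=dict)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.intensity.shape
        return (
            self.x0_um,
            self.x0_um + nx * self.pixel_size_um,
            self.y0_um,
            self.y0_um + ny * self.pixel_size_um,
        )

    def argmax_pixel(self) -> tuple[int, int]:
        """(row, col) of the intensity maximum."""
        return tuple(np.unravel_index(np.argmax(self.intensity), self.intensity.shape))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensity)

    def plot(self, ax=None, cmap: str = "magma"):
        """Render the heatmap with contour and point overlays."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(
            self.intensity,
            origin="lower",
            extent=self.extent,
            cmap=cmap,
            interpolation="bilinear",
        )
        for poly in self.contours:
            xs, ys = poly.exterior.xy
            ax.plot(xs, ys, lw=1.2, color="deepskyblue")
        for label, pts in self.point_overlays.items():
            pts = np.asarray(pts)
            if len(pts):
                ax.scatter(pts[:, 0], pts[:, 1], s=2, alpha=0.6, label=label)
        if self.point_overlays:
            ax.legend(markerscale=4, fontsize=7)
        ax.set_xlabel("x (µm)")
        ax.set_ylabel("y (µm)")
        ax.set_aspect("equal")
        return ax


def _resample_closed(poly: Polygon, n: int) -> np.ndarray:
    """Resample a polygon boundary to n vertices, equally spaced by arc
    length, starting where the boundary crosses the +x ray from its
    centroid (so congruent shapes align vertex-wise)."""
    xy = np.asarray(poly.exterior.coords)[:-1]
    cx, cy = poly.centroid.x, poly.centroid.y
    rel = xy - (cx, cy)
    # enforce counter-clockwise orientation
    area2 = np.sum(rel[:, 0] * np.roll(rel[:, 1], -1) - np.roll(rel[:, 0], -1) * rel[:, 1])
    if area2 < 0:
        rel = rel[::-1]
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    start = int(np.argmin(np.abs(ang)))
    rel = np.roll(rel, -start, axis=0)
    closed = np.vstack([rel, rel[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n, endpoint=False)
    out = np.column_stack(
        [np.interp(target, s, closed[:, 0]), np.interp(target, s, closed[:, 1])]
    )
    return out + (cx, cy)


def average_contour(per_section_polygons: Sequence[Polygon], n_vertices: int = 256) -> Polygon:
    """Vertex-wise mean outline of per-section region contours.

    Each polygon is resampled to a fixed vertex count by arc length and
    aligned on its centroid; the average contour is the vertex-wise mean
    placed at the mean centroid. One polygon returns (a resampling of)
    itself; congruent translated shapes return the shape at the mean
    position.
    """
    polys = [p for p in per_section_polygons if p is not None and not p.is_empty]
    if not polys:
        raise HistostereoError("average_contour requires at least one polygon")
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    stacks = np.stack(
        [_resample_closed(p, n_vertices) - c for p, c in zip(polys, centroids)]
    )
    mean_shape = stacks.mean(axis=0) + centroids.mean(axis=0)
    return Polygon(mean_shape)


def marker_heatmap(
    points: pd.DataFrame | np.ndarray,
    pixel_size_um: float = 50.0,
    bandwidth_um: float = 250.0,
    contours: Sequence[Polygon] | None = None,
    overlay_by_compartment: bool = False,
    pad_um: float | None = None,
) -> HeatmapGrid:
    """Coronal-plane marker density map.

    Points are projected onto (x, y), binned at ``pixel_size_um``, smoothed
    with an isotropic Gaussian kernel of standard deviation ``bandwidth_um``
    (reflecting boundary, so smoothed mass is conserved), and
    max-normalized. An empty input yields an all-zero 1×1 grid.
    """
    if pixel_size_um <= 0 or bandwidth_um <= 0:
        raise HistostereoError("pixel size and bandwidth must be positive")
    if isinstance(points, pd.DataFrame):
        xy = points[["x_um", "y_um"]].to_numpy(dtype=float)
        comp = points["compartment"].to_numpy() if "compartment" in points else None
    else:
        arr = np.atleast_2d(np.asarray(points, dtype=float))
        xy = arr[:, :2] if arr.size else np.empty((0, 2))
        comp = None

    contours = list(contours) if contours else []
    if len(xy) == 0:
        return HeatmapGrid(
            intensity=np.zeros((1, 1)),
            mass=np.zeros((1, 1)),
            pixel_size_um=pixel_size_um,
            x0_um=0.0,
            y0_um=0.0,
            contours=contours,
        )
    pad = 2.0 * bandwidth_um if pad_um is None else pad_um
    x0 = float(xy[:, 0].min()) - pad
    y0 = float(xy[:, 1].min()) - pad
    x1 = float(xy[:, 0].max()) + pad
    y1 = float(xy[:, 1].max()) + pad
    nx = max(int(np.ceil((x1 - x0) / pixel_size_um)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_size_um)), 1)
    counts, _, _ = np.histogram2d(
        xy[:, 1], xy[:, 0],
        bins=(ny, nx),
        range=((y0, y0 + ny * pixel_size_um), (x0, x0 + nx * pixel_size_um)),
    )
    sigma_px = bandwidth_um / pixel_size_um
    mass = gaussian_filter(counts, sigma=sigma_px, mode="reflect")
    peak = mass.max()
    intensity = mass / peak if peak > 0 else mass
    overlays = {}
    if overlay_by_compartment and comp is not None:
        for label in pd.unique(comp):
            overlays[str(label)] = xy[comp == label]
    return HeatmapGrid(
        intensity=intensity,
        mass=mass,
        pixel_size_um=pixel_size_um,
        x0_um=x0,
        y0_um=y0,
        contours=contours,
        point_overlays=overlays,
    )
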