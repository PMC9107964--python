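"""Planar geometry for mosaic fields.

A *mosaic field* is one rectangular acquisition window together with the XY
centroids of every segmented cell body inside it (plus optional per-cell
morphology: apparent diameter, cross-sectional area, Feret max/min).  This
module provides the three geometric primitives every downstream statistic is
built on:

* nearest-neighbor distances (XY Euclidean, no edge correction),
* window-clipped Dirichlet (Voronoi) domains with areas and edge-sharing
  neighbor counts,
* spatial density in cells/mm².

Conventions: coordinates are continuous micrometres in a half-open window
``[x_min, x_min+side_x) × [y_min, y_min+side_y)`` with the origin at the
field's lower-left corner.  The Voronoi tessellation is computed on the full
point set and clipped to the window, so infinite cells are bounded and domain
areas tessellate the window exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree
from scipy.spatial import QhullError
from shapely.geometry import Polygon, box

__all__ = [
    "Window",
    "MosaicField",
    "TessellationResult",
    "nearest_neighbor_distances",
    "dirichlet_domains",
    "field_density",
    "circle_fraction_in_window",
]

#: side length (μm) of the confocal acquisition frames this package targets
DEFAULT_SIDE_UM = 246.03

QUADRANTS = ("dorsal", "ventral", "nasal", "temporal")

# positive-length tolerance (μm) for "these two domains share an edge"
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class Window:
    """Rectangular acquisition window, micrometres."""

    x_min: float = 0.0
    y_min: float = 0.0
    side_x: float = DEFAULT_SIDE_UM
    side_y: float = DEFAULT_SIDE_UM

    def __post_init__(self) -> None:
        if not (self.side_x > 0 and self.side_y > 0):
            raise ValueError("window sides must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.side_x

    @property
    def y_max(self) -> float:
        return self.y_min + self.side_y

    @property
    def area(self) -> float:
        """Window area in μm²."""
        return self.side_x * self.side_y

    @property
    def area_mm2(self) -> float:
        return self.area * 1e-6

    def contains(self, x, y, tol: float = 1e-9) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min - tol)
            & (x <= self.x_max + tol)
            & (y >= self.y_min - tol)
            & (y <= self.y_max + tol)
        )


def _opt_array(values, n: int, name: str, positive: bool) -> Optional[np.ndarray]:
    if values is None:
        return None
    arr = np.asarray(values, dtype=float)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have one value per cell")
    if positive and arr.size and not np.all(arr > 0):
        raise ValueError(f"{name} must be strictly positive")
    return arr


@dataclass
class MosaicField:
    """One acquisition field: window, per-cell centroids and morphology."""

    x: np.ndarray
    y: np.ndarray
    window: Window = dc_field(default_factory=Window)
    field_id: str = "field"
    quadrant: Optional[str] = None
    region_index: Optional[int] = None
    diameter: Optional[np.ndarray] = None
    cross_section_area: Optional[np.ndarray] = None
    feret_max: Optional[np.ndarray] = None
    feret_min: Optional[np.ndarray] = None
    edge_included: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        n = self.x.size
        if n and not np.all(self.window.contains(self.x, self.y)):
            raise ValueError("all centroids must lie inside or on the window")
        if self.quadrant is not None and self.quadrant not in QUADRANTS:
            raise ValueError(f"quadrant must be one of {QUADRANTS}")
        if self.region_index is not None and not 1 <= int(self.region_index) <= 4:
            raise ValueError("region_index must be in 1..4 (1 = most peripheral)")
        self.diameter = _opt_array(self.diameter, n, "diameter", positive=False)
        if self.diameter is not None and self.diameter.size and np.any(self.diameter < 0):
            raise ValueError("diameter must be non-negative")
        self.cross_section_area = _opt_array(
            self.cross_section_area, n, "cross_section_area", positive=True
        )
        self.feret_max = _opt_array(self.feret_max, n, "feret_max", positive=True)
        self.feret_min = _opt_array(self.feret_min, n, "feret_min", positive=True)
        if self.feret_max is not None and self.feret_min is not None:
            if not np.all(self.feret_max >= self.feret_min - 1e-12):
                raise ValueError("feret_max must be >= feret_min for every cell")
        if self.edge_included is not None:
            self.edge_included = np.asarray(self.edge_included, dtype=bool)
            if self.edge_included.shape != (n,):
                raise ValueError("edge_included must have one flag per cell")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TessellationResult:
    """Window-clipped Dirichlet tessellation of a field.

    ``neighbor_count[i]`` counts other *cells* whose clipped domain shares a
    positive-length edge with cell i; window-boundary segments are never
    counted as neighbors, and domains meeting only at a point are not
    neighbors.  ``adjacency`` holds the symmetric neighbor index sets.
    """

    domain_area: np.ndarray
    neighbor_count: np.ndarray
    touches_boundary: np.ndarray
    adjacency: list

    @property
    def interior(self) -> np.ndarray:
        """Boolean mask of cells whose domain does not touch the window."""
        return ~self.touches_boundary


def nearest_neighbor_distances(field: MosaicField) -> np.ndarray:
    """Per-cell XY Euclidean distance to the closest other cell.

    No edge correction is applied: cells near the window border keep their
    in-window nearest neighbor.
    """
    if field.n < 2:
        raise ValueError("at least two cells required")
    tree = cKDTree(field.points)
    dist, _ = tree.query(field.points, k=2)
    return dist[:, 1]


def _mirror_points(pts: np.ndarray, w: Window) -> np.ndarray:
    """Reflect every point across each window side (bounds all Voronoi cells)."""
    x, y = pts[:, 0], pts[:, 1]
    left = np.column_stack([2 * w.x_min - x, y])
    right = np.column_stack([2 * w.x_max - x, y])
    bottom = np.column_stack([x, 2 * w.y_min - y])
    top = np.column_stack([x, 2 * w.y_max - y])
    return np.vstack([pts, left, right, bottom, top])


def dirichlet_domains(field: MosaicField) -> TessellationResult:
    """Window-clipped Dirichlet (Voronoi) domains, areas and neighbor counts.

    The Voronoi diagram is computed on the centroids augmented with their
    mirror images across the four window sides; each original cell's region is
    then finite and tiles the window, and is intersected with the window
    rectangle to guard against floating-point overhang.
    """
    n = field.n
    if n < 3:
        raise ValueError("at least three cells required for a tessellation")
    pts = field.points
    tree = cKDTree(pts)
    dup = tree.query_pairs(r=1e-9)
    if dup:
        i, j = sorted(next(iter(dup)))
        raise ValueError(f"coincident centroids: cells {i} and {j}")

    w = field.window
    win_poly = box(w.x_min, w.y_min, w.x_max, w.y_max)

    def _voronoi(p: np.ndarray) -> Voronoi:
        return Voronoi(_mirror_points(p, w))

    try:
        vor = _voronoi(pts)
    except QhullError:
        # degenerate (e.g. cocircular) configuration: retry with a 1e-9 μm
        # internal jitter; user-visible coordinates are never modified
        warnings.warn(
            "degenerate centroid configuration; applying 1e-9 um internal jitter",
            RuntimeWarning,
            stacklevel=2,
        )
        rng = np.random.default_rng(0)
        vor = _voronoi(pts + rng.normal(0.0, 1e-9, size=pts.shape))

    polys: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:  # pragma: no cover - mirrors bound all cells
            raise RuntimeError("unbounded Voronoi region despite mirroring")
        verts = vor.vertices[region]
        # scipy does not order region vertices; cells are convex, so sort by
        # angle around the generator
        ang = np.arctan2(verts[:, 1] - pts[i, 1], verts[:, 0] - pts[i, 0])
        poly = Polygon(verts[np.argsort(ang)]).intersection(win_poly)
        polys.append(poly)

    domain_area = np.array([p.area for p in polys])
    adjacency: list[set] = [set() for _ in range(n)]
    for (a, b) in vor.ridge_points:
        if a < n and b < n:
            shared = polys[a].intersection(polys[b])
            if shared.length > _EDGE_TOL:
                adjacency[a].add(int(b))
                adjacency[b].add(int(a))
    neighbor_count = np.array([len(s) for s in adjacency], dtype=int)

    # a clipped domain touches the window iff some polygon vertex lies on the
    # window boundary; tested with a distance tolerance to absorb the O(1e-12)
    # floating noise the mirror construction leaves on boundary vertices
    def _touches(p: Polygon) -> bool:
        c = np.asarray(p.exterior.coords)
        d = np.minimum.reduce(
            [c[:, 0] - w.x_min, w.x_max - c[:, 0], c[:, 1] - w.y_min, w.y_max - c[:, 1]]
        )
        return bool(d.min() < 1e-7)

    touches = np.array([_touches(p) for p in polys])
    return TessellationResult(
        domain_area=domain_area,
        neighbor_count=neighbor_count,
        touches_boundary=touches,
        adjacency=[sorted(s) for s in adjacency],
    )


def field_density(field: MosaicField) -> float:
    """Spatial density in cells per mm².

    Every cell in the field is counted, including cells flagged as included
    under the top/left-edge counting rule (the flag records the convention
    used at segmentation time; it does not change the count here).
    """
    return field.n / field.window.area_mm2


def circle_fraction_in_window(
    cx: np.ndarray, cy: np.ndarray, r: np.ndarray, window: Window
) -> np.ndarray:
    """Fraction of the circle of radius r centred at (cx, cy) lying inside the window.

    Exact analytic inclusion–exclusion over the four window sides; requires
    ``r <= min(side_x, side_y) / 2`` so that opposite sides cannot both be
    crossed (callers enforce this).  Used as the isotropic edge correction in
    the density recovery profile.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    r = np.asarray(r, dtype=float)

    def half_angle(dist):
        # half-width of the arc lying beyond a side at distance `dist`
        with np.errstate(invalid="ignore"):
            a = np.arccos(np.clip(dist / r, -1.0, 1.0))
        return np.where(dist >= r, 0.0, a)

    a_l = half_angle(cx - window.x_min)
    a_r = half_angle(window.x_max - cx)
    a_b = half_angle(cy - window.y_min)
    a_t = half_angle(window.y_max - cy)
    outside = 2.0 * (a_l + a_r + a_b + a_t)
    # corner overlaps: adjacent side arcs are centred π/2 apart on the circle
    for ax, ay in ((a_l, a_b), (a_l, a_t), (a_r, a_b), (a_r, a_t)):
        outside -= np.maximum(0.0, ax + ay - np.pi / 2.0)
    return 1.0 - outside / (2.0 * np.pi)
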