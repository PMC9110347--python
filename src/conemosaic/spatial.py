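"""Per-class spatial statistics of a cone field.

Delaunay neighbour graphs, nearest-neighbour distances (NND), Voronoi
domain areas clipped to the sampling window, border-cell exclusion, and
the regularity index (mean/SD) summarizing mosaic order.

Nearest-neighbour and Voronoi statistics are homotypic: computed within a
single cone class, as single, double and triple cones are analyzed
separately. The Delaunay graph can also be built over all classes for
mosaic-unit queries (e.g. how many double cones surround a single cone).

Border cells — those whose window-clipped Voronoi polygon touches the
window boundary, and whose NND or domain area is therefore uncertain —
are excluded from all summary statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, Voronoi, cKDTree

from .datatypes import ConeField, Window
from .errors import DegenerateFieldError

__all__ = [
    "SummaryStats",
    "MosaicStats",
    "delaunay_neighbours",
    "nearest_neighbour_distances",
    "voronoi_domains",
    "clipped_voronoi_polygons",
    "exclude_border_cells",
    "regularity_index",
    "mosaic_summary",
]


@dataclass(frozen=True)
class SummaryStats:
    """Mean/SD/min/max and regularity index of a per-cell statistic."""

    mean: float
    sd: float
    min: float
    max: float
    regularity_index: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        sd = float(np.std(values, ddof=1)) if values.size >= 2 else float("nan")
        ri = regularity_index(values) if values.size >= 2 else float("nan")
        return cls(float(np.mean(values)), sd, float(np.min(values)),
                   float(np.max(values)), ri)


@dataclass
class MosaicStats:
    """NND and Voronoi-domain summaries for one cone class.

    Summaries cover interior (non-border) cells only; the per-cell value
    collections retained for histogramming are likewise interior-only.
    """

    cone_class: str
    n_total: int
    n_interior: int
    nnd: SummaryStats
    voronoi: SummaryStats
    nnd_values: np.ndarray
    vd_values: np.ndarray

    def scalars(self) -> dict[str, float]:
        return {
            "nnd_mean": self.nnd.mean,
            "nnd_ri": self.nnd.regularity_index,
            "vd_mean": self.voronoi.mean,
            "vd_ri": self.voronoi.regularity_index,
        }


def _select(field: ConeField, cone_class: str) -> np.ndarray:
    return field.points_of(cone_class)


def delaunay_neighbours(field: ConeField, cone_class: str = "all") -> dict[int, np.ndarray]:
    """Delaunay adjacency of the selected points.

    Returns a mapping from point index (within the selection order, which
    is field order for ``"all"`` and class-subset order otherwise) to a
    sorted array of adjacent point indices.
    """
    pts = _select(field, cone_class)
    if pts.shape[0] < 3:
        raise DegenerateFieldError(
            f"Delaunay tessellation undefined for {pts.shape[0]} point(s)"
        )
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateFieldError(
            "Delaunay tessellation undefined (collinear or degenerate points)"
        ) from exc
    if tri.simplices.size == 0:
        raise DegenerateFieldError("Delaunay tessellation undefined (degenerate)")
    adj: dict[int, set[int]] = {i: set() for i in range(pts.shape[0])}
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[int(a)].add(int(b))
    return {i: np.asarray(sorted(s), dtype=int) for i, s in adj.items()}


def nearest_neighbour_distances(field: ConeField, cone_class: str) -> np.ndarray:
    """Euclidean distance from each cell to its closest same-class cell."""
    pts = _select(field, cone_class)
    if pts.shape[0] < 2:
        raise DegenerateFieldError("nearest-neighbour distance needs >= 2 points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1].astype(float)


def clipped_voronoi_polygons(points: np.ndarray, window: Window) -> list[np.ndarray]:
    """Voronoi polygons of ``points`` clipped exactly to the window.

    Implemented by mirroring the points across all four window edges, so
    that each original point's Voronoi cell in the augmented set equals
    its true cell intersected with the window (its boundary edges fall
    exactly on the window edges).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n < 1:
        return []
    w, h = window.width, window.height
    mirrored = np.vstack([
        pts,
        pts * [-1.0, 1.0],                  # across x = 0
        np.column_stack([2 * w - pts[:, 0], pts[:, 1]]),   # across x = w
        pts * [1.0, -1.0],                  # across y = 0
        np.column_stack([pts[:, 0], 2 * h - pts[:, 1]]),   # across y = h
    ])
    try:
        vor = Voronoi(mirrored)
    except QhullError as exc:
        raise DegenerateFieldError(
            "Voronoi tessellation undefined (degenerate point set)"
        ) from exc
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:  # pragma: no cover - mirroring
            raise DegenerateFieldError("unbounded Voronoi cell after mirroring")
        polys.append(vor.vertices[region])
    return polys


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_domains(field: ConeField, cone_class: str) -> np.ndarray:
    """Window-clipped Voronoi domain area (µm²) of each same-class cell."""
    pts = _select(field, cone_class)
    if pts.shape[0] < 4:
        raise DegenerateFieldError("Voronoi domains need >= 4 points")
    polys = clipped_voronoi_polygons(pts, field.window)
    return np.asarray([_polygon_area(p) for p in polys], dtype=float)


def exclude_border_cells(field: ConeField, cone_class: str,
                         tol: float | None = None) -> np.ndarray:
    """Indices (within the class subset) of interior cells.

    A cell is interior when its window-clipped, within-class Voronoi
    polygon does not touch the window boundary; border cells have
    uncertain NND and domain areas and are excluded from statistics.
    Returns an empty set when no cell qualifies (or fewer than 4 points).
    """
    pts = _select(field, cone_class)
    if pts.shape[0] < 4:
        return np.asarray([], dtype=int)
    window = field.window
    if tol is None:
        tol = 1e-7 * max(window.width, window.height)
    try:
        polys = clipped_voronoi_polygons(pts, window)
    except DegenerateFieldError:
        return np.asarray([], dtype=int)
    interior = []
    for i, poly in enumerate(polys):
        x, y = poly[:, 0], poly[:, 1]
        touches = (
            np.any(x < tol) or np.any(x > window.width - tol)
            or np.any(y < tol) or np.any(y > window.height - tol)
        )
        if not touches:
            interior.append(i)
    return np.asarray(interior, dtype=int)


def regularity_index(values) -> float:
    """Mean divided by sample SD (n−1). Zero SD gives +inf."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("regularity index needs at least 2 values")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        return float("inf")
    return float(np.mean(values)) / sd


def mosaic_summary(field: ConeField, cone_class: str) -> MosaicStats:
    """Interior-cell NND and Voronoi summaries for one cone class."""
    pts = _select(field, cone_class)
    if pts.shape[0] < 4:
        raise DegenerateFieldError(
            f"need >= 4 points of class {cone_class!r} for a mosaic summary"
        )
    nnd = nearest_neighbour_distances(field, cone_class)
    vd = voronoi_domains(field, cone_class)
    interior = exclude_border_cells(field, cone_class)
    if interior.size < 2:
        raise DegenerateFieldError(
            f"fewer than 2 interior cells of class {cone_class!r}; "
            "the field is too sparse for border-excluded statistics"
        )
    return MosaicStats(
        cone_class=cone_class,
        n_total=int(pts.shape[0]),
        n_interior=int(interior.size),
        nnd=SummaryStats.from_values(nnd[interior]),
        voronoi=SummaryStats.from_values(vd[interior]),
        nnd_values=nnd[interior],
        vd_values=vd[interior],
    )
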