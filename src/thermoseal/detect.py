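"""Warm-object detection: thresholding, clustering, polygon attributes.

The detector selects every pixel at or above a site-specific lower thermal
boundary (9 °C at the training colony), groups selected pixels into
connected clusters, and converts each cluster to a world-coordinate polygon
carrying the attributes the classifier needs: planar area (m²), mean member
temperature (°C), and solidity (polygon area / convex-hull area).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .raster import ThermalRaster

__all__ = [
    "ClassLabel",
    "BinaryGrid",
    "PixelCluster",
    "SealPolygon",
    "select_hot_pixels",
    "extract_clusters",
    "polygonize_cluster",
    "convex_hull_ratio",
]


class ClassLabel(str, Enum):
    """Detection classes: individuals, merged aggregations, or no match."""

    INDIVIDUAL_YOY = "individual_yoy"
    INDIVIDUAL_ADULT = "individual_adult"
    YOY_AGGREGATION = "yoy_aggregation"
    ADULT_AGGREGATION = "adult_aggregation"
    UNCLASSIFIED = "unclassified"

    @property
    def is_individual(self) -> bool:
        return self in (ClassLabel.INDIVIDUAL_YOY, ClassLabel.INDIVIDUAL_ADULT)

    @property
    def is_aggregation(self) -> bool:
        return self in (ClassLabel.YOY_AGGREGATION, ClassLabel.ADULT_AGGREGATION)


@dataclass
class BinaryGrid:
    """Boolean selection grid aligned with its source raster."""

    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 2:
            raise ValueError("selection grid must be 2-D")

    @property
    def count(self) -> int:
        return int(self.selected.sum())


@dataclass(frozen=True)
class PixelCluster:
    """A maximal connected set of selected grid cells.

    ``rows`` and ``cols`` are parallel index arrays; cells are unique.
    """

    rows: np.ndarray
    cols: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.cols) or len(self.rows) == 0:
            raise ValueError("cluster must hold at least one (row, col) cell")

    @property
    def cells(self) -> frozenset[tuple[int, int]]:
        return frozenset(zip(self.rows.tolist(), self.cols.tolist()))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SealPolygon:
    """A detected warm object with the attributes used for classification.

    ``area_m2`` is pixel_count x gsd² (exact for an unsimplified rasterized
    polygon). ``chull_ratio`` (solidity) is near 1 for single smooth bodies
    and lower for irregular multi-animal aggregations. ``parent_id`` is set
    on individuals carved out of an aggregation by the high-pass split.
    """

    id: int
    geometry: Polygon
    pixel_count: int
    area_m2: float
    mean_temp_c: float
    chull_ratio: float
    label: ClassLabel = ClassLabel.UNCLASSIFIED
    parent_id: int | None = None
    cells: frozenset = field(default_factory=frozenset, repr=False)


def select_hot_pixels(raster: ThermalRaster, t_min: float) -> BinaryGrid:
    """Select every valid pixel with temperature >= t_min (inclusive).

    Nodata (or NaN) cells are never selected.
    """
    if not np.isfinite(t_min):
        raise ValueError(f"t_min must be finite, got {t_min}")
    with np.errstate(invalid="ignore"):
        sel = raster.valid_mask & (raster.values >= t_min)
    return BinaryGrid(selected=sel)


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def extract_clusters(binary: BinaryGrid, connectivity: int = 4) -> list[PixelCluster]:
    """Partition selected cells into maximal connected clusters.

    ``connectivity`` 4 joins edge-sharing cells only (the GIS
    raster-to-polygon default); 8 also joins diagonal neighbors.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(binary.selected, structure=_STRUCTURES[connectivity])
    clusters = []
    if n:
        order = np.argsort(labels.ravel(), kind="stable")
        flat = labels.ravel()[order]
        starts = np.searchsorted(flat, np.arange(1, n + 1))
        ends = np.searchsorted(flat, np.arange(1, n + 1), side="right")
        nrows, ncols = labels.shape
        rr, cc = np.divmod(order, ncols)
        for s, e in zip(starts, ends):
            clusters.append(PixelCluster(rows=rr[s:e], cols=cc[s:e]))
    return clusters


def _cluster_geometry(cluster: PixelCluster, raster: ThermalRaster) -> Polygon:
    """Union of member pixel squares in world coordinates.

    Consecutive columns within a row are merged into one rectangle before
    the union, which keeps the union cheap for large clusters.
    """
    t = raster.transform
    rects = []
    order = np.lexsort((cluster.cols, cluster.rows))
    rows = cluster.rows[order]
    cols = cluster.cols[order]
    i = 0
    n = len(rows)
    while i < n:
        r, c0 = rows[i], cols[i]
        j = i
        while j + 1 < n and rows[j + 1] == r and cols[j + 1] == cols[j] + 1:
            j += 1
        x0, y0 = t.corner(r, c0)          # NW corner of run start
        x1, y1 = t.corner(r + 1, cols[j] + 1)  # SE corner of run end
        rects.append(box(x0, y1, x1, y0))
        i = j + 1
    geom = unary_union(rects)
    if geom.geom_type == "MultiPolygon":  # cannot happen for a connected cluster
        geom = max(geom.geoms, key=lambda g: g.area)
    return geom


def polygonize_cluster(cluster: PixelCluster, raster: ThermalRaster,
                       poly_id: int = 0, parent_id: int | None = None) -> SealPolygon:
    """Convert a pixel cluster to an attributed world-coordinate polygon."""
    geom = _cluster_geometry(cluster, raster)
    temps = raster.values[cluster.rows, cluster.cols]
    pixel_count = len(cluster)
    area = pixel_count * raster.gsd_m ** 2
    return SealPolygon(
        id=poly_id,
        geometry=geom,
        pixel_count=pixel_count,
        area_m2=area,
        mean_temp_c=float(np.mean(temps)),
        chull_ratio=convex_hull_ratio(geom),
        parent_id=parent_id,
        cells=cluster.cells,
    )


def convex_hull_ratio(polygon: Polygon) -> float:
    """Solidity: polygon area divided by the area of its convex hull.

    Equals 1 for convex shapes; drops toward 0 as the outline grows more
    irregular. Holes reduce the polygon area but not the hull area.
    """
    if polygon.area <= 0:
        raise ValueError("convex hull ratio undefined for zero-area geometry")
    return polygon.area / polygon.convex_hull.area
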