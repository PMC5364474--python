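"""High-pass filtering and aggregation splitting.

Seals huddled together threshold into a single merged polygon. Inside such
an aggregation each animal still has a warm core and the contact seams
between bodies are cooler, so a zero-sum 3x3 high-pass convolution of the
*continuous* temperatures responds positively at the cores and negatively
(or near zero) along seams and flat background. Selecting the
positive-response cells within the aggregation footprint and re-extracting
connected components therefore carves the aggregation into individuals.

Individuals carved from an adult aggregation are labeled adults, and those
from a YOY aggregation are labeled YOY; no re-classification is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import ndimage

from .classify import ClassificationParams
from .detect import (
    BinaryGrid,
    ClassLabel,
    PixelCluster,
    SealPolygon,
    extract_clusters,
    polygonize_cluster,
)
from .raster import ThermalRaster

__all__ = ["FilterKernel", "default_kernel", "high_pass", "split_aggregation"]


@dataclass(frozen=True)
class FilterKernel:
    """Zero-sum 3x3 high-pass kernel with a positive center weight."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        object.__setattr__(self, "weights", w)
        if w.shape != (3, 3):
            raise ValueError(f"kernel must be 3x3, got shape {w.shape}")
        if abs(w.sum()) > 1e-9 * max(1.0, np.abs(w).sum()):
            raise ValueError(f"kernel weights must sum to zero, got {w.sum()}")
        if w[1, 1] <= 0:
            raise ValueError("kernel center weight must be positive")


def default_kernel() -> FilterKernel:
    """Standard GIS 3x3 high-pass: center 6.8, edges -1.0, corners -0.7."""
    return FilterKernel(np.array([
        [-0.7, -1.0, -0.7],
        [-1.0, 6.8, -1.0],
        [-0.7, -1.0, -0.7],
    ]))


def _fill_nodata_nearest(raster: ThermalRaster) -> np.ndarray:
    """Replace nodata cells with the nearest valid temperature."""
    values = raster.values
    valid = raster.valid_mask
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("raster has no valid cells to filter")
    idx = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    return values[tuple(idx)]


def high_pass(raster: ThermalRaster, kernel: FilterKernel | None = None) -> np.ndarray:
    """Convolve the raster with a zero-sum high-pass kernel.

    Nodata cells are filled with their nearest valid value first and the
    grid edge is extended by replication, so a spatially constant scene
    yields an identically zero response. Returns a float grid of the same
    shape (°C-weighted response).
    """
    if kernel is None:
        kernel = default_kernel()
    filled = _fill_nodata_nearest(raster)
    return ndimage.convolve(filled, kernel.weights, mode="nearest")


def split_aggregation(
    agg: SealPolygon,
    raster: ThermalRaster,
    params: ClassificationParams,
    kernel: FilterKernel | None = None,
    connectivity: int = 4,
    start_id: int = 0,
) -> list[SealPolygon]:
    """Break an aggregation polygon into individual seals.

    The filter runs on the aggregation's own temperatures: within the
    footprint's bounding box, cells outside the footprint are filled with
    the nearest footprint temperature before convolution. This removes the
    footprint's outer body-to-ambient edge — which would otherwise dominate
    the response as one connected warm rim — so the response reflects only
    internal structure: positive at member cores, negative along the cooler
    contact seams.

    Cells of the footprint with a strictly positive response are selected
    and connected components extracted with the same connectivity as
    detection. Each component becomes an individual with
    ``parent_id = agg.id`` and the class implied by the parent (adult
    aggregation -> adults, YOY aggregation -> YOY). A footprint with no
    positive response (e.g. a perfectly uniform blob) falls back to a single
    individual covering the whole aggregation — a warm object above
    threshold is at least one animal.

    Output ids run from ``start_id``.
    """
    if not agg.label.is_aggregation:
        raise ValueError(
            f"polygon {agg.id} has label {agg.label.value}; only aggregations can be split"
        )
    if not agg.cells:
        raise ValueError(f"aggregation {agg.id} carries no footprint cells")
    if kernel is None:
        kernel = default_kernel()

    child_label = (ClassLabel.INDIVIDUAL_ADULT
                   if agg.label is ClassLabel.ADULT_AGGREGATION
                   else ClassLabel.INDIVIDUAL_YOY)

    rows = np.fromiter((r for r, _ in agg.cells), dtype=np.intp)
    cols = np.fromiter((c for _, c in agg.cells), dtype=np.intp)

    # local window: footprint bbox padded for the 3x3 convolution support
    pad = 2
    r0 = max(0, int(rows.min()) - pad)
    r1 = min(raster.shape[0], int(rows.max()) + pad + 1)
    c0 = max(0, int(cols.min()) - pad)
    c1 = min(raster.shape[1], int(cols.max()) + pad + 1)
    local_foot = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local_foot[rows - r0, cols - c0] = True

    window = raster.values[r0:r1, c0:c1]
    idx = ndimage.distance_transform_edt(~local_foot, return_distances=False,
                                         return_indices=True)
    extended = window[tuple(idx)]
    local_resp = ndimage.convolve(extended, kernel.weights, mode="nearest")

    # strict "response > 0" up to float roundoff: a zero-sum kernel over a
    # flat region returns O(eps) noise of either sign, not exact zero
    tol = 1e-9 * (1.0 + float(np.abs(extended).max()))
    selected = np.zeros(raster.shape, dtype=bool)
    selected[r0:r1, c0:c1] = local_foot & (local_resp > tol)
    clusters = extract_clusters(BinaryGrid(selected), connectivity=connectivity)

    if not clusters:
        solo = dc_replace(agg, id=start_id, label=child_label, parent_id=agg.id)
        return [solo]

    out = []
    for i, cluster in enumerate(clusters):
        poly = polygonize_cluster(cluster, raster, poly_id=start_id + i,
                                  parent_id=agg.id)
        poly.label = child_label
        out.append(poly)
    return out
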