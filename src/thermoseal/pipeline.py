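"""End-to-end detection pipeline.

Orchestrates the full flow: exclusion masking, thermal thresholding,
connected-component clustering, polygon attribution, rule-based
classification, high-pass splitting of aggregations, and counting. Per-stage
object counts are logged so discrepancies against human counts can be
localized to a stage.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .assess import CountSummary, count_summary
from .classify import ClassificationParams, classify
from .detect import ClassLabel, SealPolygon, extract_clusters, polygonize_cluster, select_hot_pixels
from .filters import FilterKernel, default_kernel, split_aggregation
from .raster import ExclusionMask, ThermalRaster, apply_exclusion_mask

__all__ = ["DetectionResult", "run_pipeline"]

logger = logging.getLogger("thermoseal")


@dataclass
class DetectionResult:
    """Pipeline output: individual detections plus stage bookkeeping.

    ``detections`` holds only individual-labeled polygons (direct
    individuals and aggregation-split children). ``aggregates_found`` is the
    number of aggregation polygons before splitting; ``unclassified`` are
    polygons matching no classification rule, excluded from counts but kept
    for inspection.
    """

    detections: list[SealPolygon]
    aggregates_found: int
    unclassified: list[SealPolygon]
    counts: CountSummary
    provenance: dict = field(default_factory=dict)


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def run_pipeline(
    raster: ThermalRaster,
    mask: ExclusionMask | None = None,
    params: ClassificationParams | None = None,
    kernel: FilterKernel | None = None,
    connectivity: int = 4,
) -> DetectionResult:
    """Run mask -> threshold -> cluster -> classify -> split -> count.

    Deterministic for fixed inputs. The detection threshold, rule mode and
    temperature offset come from ``params`` (defaults: 9 °C, complex, no
    offset); ``kernel`` defaults to the standard 3x3 high-pass.
    """
    if params is None:
        params = ClassificationParams()
    if kernel is None:
        kernel = default_kernel()

    checksum = hashlib.sha256(np.ascontiguousarray(raster.values).tobytes()).hexdigest()

    if mask is not None:
        raster = _stage("mask", apply_exclusion_mask, raster, mask)

    grid = _stage("threshold", select_hot_pixels, raster, params.detect_threshold_c)
    logger.info("threshold %.2f degC: %d pixels selected", params.detect_threshold_c, grid.count)

    clusters = _stage("cluster", extract_clusters, grid, connectivity)
    logger.info("clustering (connectivity %d): %d clusters", connectivity, len(clusters))

    polygons = [
        _stage("polygonize", polygonize_cluster, cl, raster, poly_id=i)
        for i, cl in enumerate(clusters)
    ]
    for poly in polygons:
        poly.label = _stage("classify", classify, poly, params)

    individuals = [p for p in polygons if p.label.is_individual]
    aggregations = [p for p in polygons if p.label.is_aggregation]
    unclassified = [p for p in polygons if p.label is ClassLabel.UNCLASSIFIED]
    logger.info("classified: %d individuals, %d aggregations, %d unclassified",
                len(individuals), len(aggregations), len(unclassified))
    for poly in unclassified:
        logger.warning(
            "polygon %d unclassified (area %.3f m2, meanT %.2f degC, ratio %.3f)",
            poly.id, poly.area_m2, poly.mean_temp_c, poly.chull_ratio)

    detections = list(individuals)
    if aggregations:
        next_id = max(p.id for p in polygons) + 1
        for agg in aggregations:
            children = _stage("split", split_aggregation, agg, raster, params,
                              kernel=kernel, connectivity=connectivity,
                              start_id=next_id)
            logger.info("aggregation %d (%s) split into %d individuals",
                        agg.id, agg.label.value, len(children))
            next_id += len(children)
            detections.extend(children)

    counts = _stage("count", count_summary, detections)
    logger.info("counts: %d YOY + %d adults = %d seals",
                counts.n_yoy, counts.n_adult, counts.n_total)

    provenance = {
        "raster_sha256": checksum,
        "raster_shape": list(raster.shape),
        "gsd_m": raster.gsd_m,
        "crs": f"EPSG:{raster.crs}",
        "params": asdict(params),
        "kernel": np.asarray(kernel.weights).ravel().tolist(),
        "connectivity": connectivity,
        "masked": mask is not None,
    }
    return DetectionResult(
        detections=detections,
        aggregates_found=len(aggregations),
        unclassified=unclassified,
        counts=counts,
        provenance=provenance,
    )
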