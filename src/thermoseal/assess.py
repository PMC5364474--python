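"""Accuracy assessment against human annotation points.

Model predictions are compared to class-labeled points placed by human
analysts. Because hand-placed points carry a small GPS error, points within
a snap radius (default 0.5 m) of a prediction polygon are first moved to the
nearest location within that polygon; points are then spatially joined to
polygons, and each prediction polygon is tabulated as a true positive or one
of four false-positive categories. Human points contained in no prediction
are "missed by model".
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import pandas as pd
from shapely.geometry import Point
from shapely.ops import nearest_points

from .detect import ClassLabel, SealPolygon

__all__ = [
    "GroundTruthPoint",
    "MatchConfig",
    "CountSummary",
    "ClassAccuracy",
    "AccuracyTable",
    "count_summary",
    "snap_points",
    "accuracy_assessment",
]

_POINT_LABELS = ("adult", "yoy")
_LABEL_TO_POINT = {
    ClassLabel.INDIVIDUAL_YOY: "yoy",
    ClassLabel.INDIVIDUAL_ADULT: "adult",
}


@dataclass(frozen=True)
class GroundTruthPoint:
    """A human-placed annotation: location plus adult/yoy class."""

    id: int
    x: float
    y: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in _POINT_LABELS:
            raise ValueError(f"point label must be one of {_POINT_LABELS}, got {self.label!r}")
        if not (abs(self.x) < float("inf") and abs(self.y) < float("inf")):
            raise ValueError("point coordinates must be finite")

    @property
    def geometry(self) -> Point:
        return Point(self.x, self.y)


@dataclass(frozen=True)
class MatchConfig:
    """Matching configuration; ``snap_radius_m`` is the GPS-error allowance."""

    snap_radius_m: float = 0.5

    def __post_init__(self) -> None:
        if self.snap_radius_m < 0:
            raise ValueError("snap_radius_m must be >= 0")


@dataclass(frozen=True)
class CountSummary:
    """Census totals: individual YOY + individual adults."""

    n_yoy: int
    n_adult: int

    @property
    def n_total(self) -> int:
        return self.n_yoy + self.n_adult

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": ["Total Juveniles", "Total Adults", "Total Seals"],
             "count": [self.n_yoy, self.n_adult, self.n_total]}
        )


def count_summary(detections: list[SealPolygon]) -> CountSummary:
    """Count individual YOY and adult polygons; unclassified are excluded.

    Raises if any aggregation label remains (splitting was not run).
    """
    n = {ClassLabel.INDIVIDUAL_YOY: 0, ClassLabel.INDIVIDUAL_ADULT: 0}
    for det in detections:
        if det.label.is_aggregation:
            raise ValueError(
                f"detection {det.id} still labeled {det.label.value}: "
                "run aggregation splitting before counting"
            )
        if det.label.is_individual:
            n[det.label] += 1
    return CountSummary(n_yoy=n[ClassLabel.INDIVIDUAL_YOY],
                        n_adult=n[ClassLabel.INDIVIDUAL_ADULT])


def snap_points(points: list[GroundTruthPoint], detections: list[SealPolygon],
                cfg: MatchConfig = MatchConfig()) -> list[GroundTruthPoint]:
    """Move near-miss points inside their nearest prediction polygon.

    A point already inside (or on the boundary of) any detection is
    unchanged. A point outside all detections but within ``snap_radius_m``
    of the nearest one is relocated to the closest location within that
    polygon. Distance ties are broken by lowest polygon id. Points farther
    than the radius from every polygon are unchanged, so the operation is
    idempotent.
    """
    if not detections:
        return list(points)
    out = []
    for pt in points:
        geom = pt.geometry
        if any(det.geometry.covers(geom) for det in detections):
            out.append(pt)
            continue
        best = min(detections, key=lambda det: (det.geometry.distance(geom), det.id))
        dist = best.geometry.distance(geom)
        if dist <= cfg.snap_radius_m:
            target = nearest_points(best.geometry, geom)[0]
            out.append(dc_replace(pt, x=target.x, y=target.y))
        else:
            out.append(pt)
    return out


@dataclass(frozen=True)
class ClassAccuracy:
    """Per-class tabulation of prediction-polygon outcomes.

    The four prediction-side counts partition the predictions of the class,
    so their proportions sum to 1. ``missed_by_model`` counts human points
    of this class contained in no prediction polygon.
    """

    true_positive: int = 0
    confused_with_other_class: int = 0
    confused_with_aggregation_derived: int = 0
    confused_with_adult_yoy_pair: int = 0
    not_detected_by_humans: int = 0
    missed_by_model: int = 0

    @property
    def n_predictions(self) -> int:
        return (self.true_positive + self.confused_with_other_class
                + self.confused_with_aggregation_derived
                + self.confused_with_adult_yoy_pair + self.not_detected_by_humans)

    def proportions(self) -> dict[str, float]:
        n = self.n_predictions
        if n == 0:
            return {k: 0.0 for k in ("true_positive", "confused_with_other_class",
                                     "confused_with_aggregation_derived",
                                     "confused_with_adult_yoy_pair",
                                     "not_detected_by_humans")}
        return {
            "true_positive": self.true_positive / n,
            "confused_with_other_class": self.confused_with_other_class / n,
            "confused_with_aggregation_derived": self.confused_with_aggregation_derived / n,
            "confused_with_adult_yoy_pair": self.confused_with_adult_yoy_pair / n,
            "not_detected_by_humans": self.not_detected_by_humans / n,
        }


@dataclass(frozen=True)
class AccuracyTable:
    """Confusion categories for YOY and adult prediction polygons."""

    yoy: ClassAccuracy
    adult: ClassAccuracy

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cls_name, acc in (("yoy", self.yoy), ("adult", self.adult)):
            props = acc.proportions()
            other = "adult" if cls_name == "yoy" else "yoy"
            rows += [
                (cls_name, "True Positive", acc.true_positive, props["true_positive"]),
                (cls_name, f"False Positive: Confused with {other}",
                 acc.confused_with_other_class, props["confused_with_other_class"]),
                (cls_name, "False Positive: Confused with Aggregation",
                 acc.confused_with_aggregation_derived,
                 props["confused_with_aggregation_derived"]),
                (cls_name, "False Positive: Confused with Adult and Juvenile Pair",
                 acc.confused_with_adult_yoy_pair, props["confused_with_adult_yoy_pair"]),
                (cls_name, "False Positive: Not Detected by Humans",
                 acc.not_detected_by_humans, props["not_detected_by_humans"]),
                (cls_name, "Human-Identified Not Detected By Model",
                 acc.missed_by_model, float("nan")),
            ]
        return pd.DataFrame(rows, columns=["class", "result", "count", "proportion"])


def accuracy_assessment(points: list[GroundTruthPoint],
                        detections: list[SealPolygon],
                        cfg: MatchConfig = MatchConfig()) -> AccuracyTable:
    """Spatially join snapped points to individual prediction polygons.

    Each point is assigned to at most one polygon (the lowest-id polygon
    covering it), so every point is counted exactly once — inside some
    polygon's category or as missed. Per polygon of predicted class c:

    - contains points of both classes -> confused with an adult/YOY pair
      (a mother adjacent to her pup, merged in one aggregation);
    - contains a point of class c -> true positive;
    - contains only other-class points -> confused with the source
      aggregation when the polygon was carved from one (``parent_id`` set),
      otherwise plain confusion with the other class;
    - contains no point -> not detected by humans.

    A polygon containing several points of its own class still counts once:
    it is a single prediction.
    """
    preds = sorted((d for d in detections if d.label.is_individual), key=lambda d: d.id)
    assigned: dict[int, list[GroundTruthPoint]] = {d.id: [] for d in preds}
    missed = {"yoy": 0, "adult": 0}

    for pt in points:
        geom = pt.geometry
        holder = next((d for d in preds if d.geometry.covers(geom)), None)
        if holder is None:
            missed[pt.label] += 1
        else:
            assigned[holder.id].append(pt)

    tallies = {"yoy": dict.fromkeys(
        ("true_positive", "confused_with_other_class",
         "confused_with_aggregation_derived", "confused_with_adult_yoy_pair",
         "not_detected_by_humans"), 0)}
    tallies["adult"] = dict(tallies["yoy"])

    for det in preds:
        cls = _LABEL_TO_POINT[det.label]
        labels = {p.label for p in assigned[det.id]}
        if not labels:
            tallies[cls]["not_detected_by_humans"] += 1
        elif labels == {"adult", "yoy"}:
            tallies[cls]["confused_with_adult_yoy_pair"] += 1
        elif cls in labels:
            tallies[cls]["true_positive"] += 1
        elif det.parent_id is not None:
            tallies[cls]["confused_with_aggregation_derived"] += 1
        else:
            tallies[cls]["confused_with_other_class"] += 1

    return AccuracyTable(
        yoy=ClassAccuracy(missed_by_model=missed["yoy"], **tallies["yoy"]),
        adult=ClassAccuracy(missed_by_model=missed["adult"], **tallies["adult"]),
    )
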