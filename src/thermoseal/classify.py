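"""Rule-based classification of detected polygons.

Each thresholded polygon is assigned one of four classes — individual YOY
(young-of-the-year pup), individual adult, YOY aggregation, adult
aggregation — from its planar area, mean temperature and solidity. Two rule
variants exist: the *complex* model uses temperature to separate warm large
pups from cool small adults; the *simplified* model drops temperature and
uses area and shape only.

When the rule set trained at one site is applied at a colder site, the
temperature split is shifted by the difference between the two sites' lower
detection thresholds (e.g. 5.5 − 9.0 = −3.5 °C), on the assumption that the
whole thermal scene is offset by the ambient difference.

Rules are evaluated in a fixed precedence order (individual YOY, individual
adult, YOY aggregation, adult aggregation); the first match wins and a
polygon matching no rule is left unclassified. The printed thresholds are
deliberately asymmetric in strictness (``area <= 0.85`` for individuals but
``area < 0.85`` for aggregations), so a handful of boundary values can fall
through; those polygons are reported rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .detect import ClassLabel, SealPolygon

__all__ = ["ClassificationParams", "classify", "offset_temperature"]

_TRAINING_THRESHOLD_C = 9.0  # lower thermal boundary at the training colony


@dataclass(frozen=True)
class ClassificationParams:
    """All classifier thresholds plus detection threshold and mode.

    Defaults are the trained values: area boundaries 0.65 / 0.85 / 3.5 m²,
    solidity boundaries 0.75 / 0.8, temperature split 10 °C, detection
    threshold 9 °C, complex mode, no offset.
    """

    mode: str = "complex"
    detect_threshold_c: float = 9.0
    yoy_area_max_m2: float = 0.85
    yoy_small_area_m2: float = 0.65
    adult_area_max_m2: float = 3.5
    ratio_individual_min: float = 0.8
    ratio_yoy_agg_max: float = 0.75
    temp_split_c: float = 10.0
    temp_offset_c: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("simplified", "complex"):
            raise ValueError(f"mode must be 'simplified' or 'complex', got {self.mode!r}")
        if not (0 < self.yoy_small_area_m2 < self.yoy_area_max_m2 < self.adult_area_max_m2):
            raise ValueError("area thresholds must satisfy 0 < small < yoy_max < adult_max")
        if not (0 < self.ratio_yoy_agg_max <= self.ratio_individual_min <= 1):
            raise ValueError("ratio thresholds must satisfy 0 < yoy_agg_max <= individual_min <= 1")

    @property
    def effective_temp_split_c(self) -> float:
        """The temperature split actually applied: ``temp_split_c + temp_offset_c``."""
        return self.temp_split_c + self.temp_offset_c

    @classmethod
    def for_site(cls, detect_threshold_c: float, mode: str = "complex",
                 temp_offset_c: float | None = None, **kwargs) -> "ClassificationParams":
        """Parameters for a new site given its lower detection threshold.

        In complex mode the temperature offset defaults to
        ``detect_threshold_c − 9.0`` (the difference from the training
        site's threshold), reproducing the cross-site transfer rule; pass
        ``temp_offset_c`` explicitly to decouple the two.
        """
        if temp_offset_c is None:
            temp_offset_c = detect_threshold_c - _TRAINING_THRESHOLD_C if mode == "complex" else 0.0
        return cls(mode=mode, detect_threshold_c=detect_threshold_c,
                   temp_offset_c=temp_offset_c, **kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "ClassificationParams":
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # flat key: value config

            data = yaml.safe_load(text)
        return cls(**data)


def classify(polygon: SealPolygon, params: ClassificationParams) -> ClassLabel:
    """Assign a class to one polygon; pure in (area, meanT, ratio, params).

    Inequalities are exactly the trained rule set, including the strict /
    non-strict asymmetries; no rule matching yields ``UNCLASSIFIED``.
    """
    area = polygon.area_m2
    temp = polygon.mean_temp_c
    ratio = polygon.chull_ratio
    for name, val in (("area_m2", area), ("mean_temp_c", temp), ("chull_ratio", ratio)):
        if val is None:
            raise ValueError(f"polygon {polygon.id}: attribute {name} is unset")

    p = params
    t_star = p.effective_temp_split_c

    if p.mode == "complex":
        yoy = (area <= p.yoy_area_max_m2 and temp < t_star) or area < p.yoy_small_area_m2
    else:
        yoy = area <= p.yoy_area_max_m2
    if yoy:
        return ClassLabel.INDIVIDUAL_YOY

    if p.mode == "complex":
        adult = (
            (p.yoy_small_area_m2 < area <= p.adult_area_max_m2
             and ratio > p.ratio_individual_min and temp > t_star)
            or (p.yoy_area_max_m2 < area <= p.adult_area_max_m2
                and ratio > p.ratio_individual_min)
        )
    else:
        adult = (p.yoy_area_max_m2 < area <= p.adult_area_max_m2
                 and ratio > p.ratio_individual_min)
    if adult:
        return ClassLabel.INDIVIDUAL_ADULT

    if ((p.yoy_small_area_m2 < area < p.yoy_area_max_m2 and ratio < p.ratio_yoy_agg_max)
            or (p.yoy_area_max_m2 < area < p.adult_area_max_m2
                and ratio < p.ratio_individual_min)):
        return ClassLabel.YOY_AGGREGATION

    if area > p.adult_area_max_m2 and ratio < p.ratio_individual_min:
        return ClassLabel.ADULT_AGGREGATION

    return ClassLabel.UNCLASSIFIED


def offset_temperature(params: ClassificationParams, delta: float) -> ClassificationParams:
    """Return params with the temperature offset incremented by ``delta`` °C."""
    import math

    if not math.isfinite(delta):
        raise ValueError(f"offset delta must be finite, got {delta}")
    return dataclasses.replace(params, temp_offset_c=params.temp_offset_c + delta)
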