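import pytest
from shapely.geometry import Polygon

from thermoseal import (
    ClassLabel,
    CountSummary,
    GroundTruthPoint,
    MatchConfig,
    SealPolygon,
    accuracy_assessment,
    count_summary,
    snap_points,
)


def det(i, label, x0=0.0, y0=0.0, size=1.0, parent=None):
    geom = Polygon([(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size)])
    return SealPolygon(i, geom, 4, size * size, 12.0, 1.0, label, parent_id=parent)


YOY, ADULT = ClassLabel.INDIVIDUAL_YOY, ClassLabel.INDIVIDUAL_ADULT


class TestCountSummary:
    def test_empty(self):
        assert count_summary([]) == CountSummary(0, 0)

    def test_counts_by_class_and_total(self):
        dets = [det(i, YOY) for i in range(3)] + [det(i + 3, ADULT) for i in range(2)]
        cs = count_summary(dets)
        assert (cs.n_yoy, cs.n_adult, cs.n_total) == (3, 2, 5)

    def test_unclassified_excluded(self):
        dets = [det(0, YOY), det(1, ClassLabel.UNCLASSIFIED)]
        assert count_summary(dets).n_total == 1

    def test_remaining_aggregation_rejected(self):
        with pytest.raises(ValueError, match="splitting"):
            count_summary([det(0, ClassLabel.ADULT_AGGREGATION)])


class TestSnapPoints:
    def test_point_inside_polygon_unchanged(self):
        pts = [GroundTruthPoint(0, 0.5, 0.5, "yoy")]
        out = snap_points(pts, [det(0, YOY)])
        assert (out[0].x, out[0].y) == (0.5, 0.5)

    def test_near_point_relocated_into_nearest_polygon(self):
        pts = [GroundTruthPoint(0, 1.3, 0.5, "yoy")]
        out = snap_points(pts, [det(0, YOY)])
        moved = out[0]
        assert det(0, YOY).geometry.covers(moved.geometry)
        d = ((moved.x - 1.3) ** 2 + (moved.y - 0.5) ** 2) ** 0.5
        assert d <= 0.3 + 1e-9

    def test_far_point_unchanged(self):
        pts = [GroundTruthPoint(0, 1.6, 0.5, "yoy")]
        out = snap_points(pts, [det(0, YOY)])
        assert (out[0].x, out[0].y) == (1.6, 0.5)

    def test_snapping_is_idempotent(self):
        pts = [GroundTruthPoint(0, 1.3, 0.5, "yoy"),
               GroundTruthPoint(1, 1.6, 0.5, "adult"),
               GroundTruthPoint(2, 0.2, 0.2, "yoy")]
        dets = [det(0, YOY), det(1, ADULT, x0=3.0)]
        once = snap_points(pts, dets)
        twice = snap_points(once, dets)
        assert [(p.x, p.y) for p in once] == [(p.x, p.y) for p in twice]

    def test_tie_broken_by_lowest_polygon_id(self):
        # point equidistant from two polygons
        dets = [det(0, YOY), det(1, YOY, x0=2.0)]
        pts = [GroundTruthPoint(0, 1.5, 0.5, "yoy")]
        out = snap_points(pts, dets)
        assert dets[0].geometry.covers(out[0].geometry)

    def test_no_detections_is_identity(self):
        pts = [GroundTruthPoint(0, 1.0, 1.0, "adult")]
        assert snap_points(pts, []) == pts

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            MatchConfig(snap_radius_m=-0.1)


class TestAccuracyAssessment:
    def test_matching_point_is_true_positive(self):
        table = accuracy_assessment(
            [GroundTruthPoint(0, 0.5, 0.5, "yoy")], [det(0, YOY)])
        assert table.yoy.true_positive == 1
        assert table.yoy.n_predictions == 1
        assert table.adult.n_predictions == 0
        assert table.yoy.missed_by_model == 0

    def test_other_class_point_in_plain_polygon(self):
        table = accuracy_assessment(
            [GroundTruthPoint(0, 0.5, 0.5, "yoy")], [det(0, ADULT)])
        assert table.adult.confused_with_other_class == 1
        assert table.adult.true_positive == 0

    def test_other_class_point_in_aggregation_derived_polygon(self):
        table = accuracy_assessment(
            [GroundTruthPoint(0, 0.5, 0.5, "adult")], [det(0, YOY, parent=9)])
        assert table.yoy.confused_with_aggregation_derived == 1
        assert table.yoy.confused_with_other_class == 0

    def test_adult_and_yoy_pair_in_one_polygon(self):
        pts = [GroundTruthPoint(0, 0.3, 0.5, "adult"),
               GroundTruthPoint(1, 0.7, 0.5, "yoy")]
        table = accuracy_assessment(pts, [det(0, YOY, parent=9)])
        assert table.yoy.confused_with_adult_yoy_pair == 1
        assert table.yoy.true_positive == 0

    def test_empty_polygon_not_detected_by_humans(self):
        table = accuracy_assessment([], [det(0, YOY)])
        assert table.yoy.not_detected_by_humans == 1

    def test_unmatched_point_is_missed_by_model(self):
        table = accuracy_assessment(
            [GroundTruthPoint(0, 5.0, 5.0, "adult")], [det(0, YOY)])
        assert table.adult.missed_by_model == 1
        assert table.yoy.not_detected_by_humans == 1

    def test_two_own_class_points_count_once(self):
        pts = [GroundTruthPoint(0, 0.3, 0.5, "yoy"),
               GroundTruthPoint(1, 0.7, 0.5, "yoy")]
        table = accuracy_assessment(pts, [det(0, YOY)])
        assert table.yoy.true_positive == 1
        assert table.yoy.n_predictions == 1

    def test_prediction_and_point_conservation(self):
        dets = [det(0, YOY), det(1, ADULT, x0=2.0), det(2, YOY, x0=4.0, parent=7),
                det(3, ADULT, x0=6.0)]
        pts = [GroundTruthPoint(0, 0.5, 0.5, "yoy"),      # TP yoy
               GroundTruthPoint(1, 2.5, 0.5, "yoy"),      # adult confused
               GroundTruthPoint(2, 4.5, 0.5, "adult"),    # yoy agg-derived confused
               GroundTruthPoint(3, 9.0, 9.0, "adult"),    # missed
               GroundTruthPoint(4, 6.5, 0.5, "adult"),    # TP adult
               GroundTruthPoint(5, 6.6, 0.4, "yoy")]      # same polygon: pair
        table = accuracy_assessment(pts, dets)
        # prediction-side: every polygon in exactly one category per class
        assert table.yoy.n_predictions == 2
        assert table.adult.n_predictions == 2
        # point-side: every point counted once
        tallied = (table.yoy.true_positive + table.yoy.confused_with_aggregation_derived
                   + table.adult.confused_with_other_class
                   + 2 * table.adult.confused_with_adult_yoy_pair
                   + table.adult.missed_by_model)
        assert tallied == len(pts)
        props = table.yoy.proportions()
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_proportions_sum_to_one_per_class(self):
        dets = [det(0, YOY), det(1, YOY, x0=2.0), det(2, ADULT, x0=4.0)]
        pts = [GroundTruthPoint(0, 0.5, 0.5, "yoy")]
        table = accuracy_assessment(pts, dets)
        assert sum(table.yoy.proportions().values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(table.adult.proportions().values()) == pytest.approx(1.0, abs=1e-9)

    def test_table_dataframe_layout(self):
        table = accuracy_assessment(
            [GroundTruthPoint(0, 0.5, 0.5, "yoy")], [det(0, YOY)])
        df = table.to_dataframe()
        assert set(df["class"]) == {"yoy", "adult"}
        assert len(df) == 12  # six rows per class
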