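"""Consecutive-change extraction, polar transform, exclusion zone, statistics."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from coagree import (
    DeltaPair, Timepoint, TrendAnalysis, consecutive_changes, exclusion_threshold,
    exclusion_threshold_from_mean, polar_statistics, polar_transform,
)

from conftest import make_sample

delta_values = st.floats(min_value=-10.0, max_value=10.0, allow_nan=False)


def dp(delta_ref, delta_test):
    return DeltaPair("S1", Timepoint.BASELINE, Timepoint.ROSC15, delta_ref, delta_test)


def rotation_oracle(delta_ref, delta_test):
    """Independent check: reflect onto positive mean change, rotate the
    coordinate frame by 45 degrees, read the polar angle directly."""
    s = (delta_ref + delta_test) / 2.0
    if s < 0:
        delta_ref, delta_test = -delta_ref, -delta_test
    c = math.cos(math.radians(45.0))
    x = c * delta_ref + c * delta_test   # coordinate along the identity line
    y = -c * delta_ref + c * delta_test  # perpendicular deviation
    angle = math.degrees(math.atan2(y, x))
    if angle <= -90.0 + 1e-12:
        angle += 180.0
    return angle, abs(s)


class TestConsecutiveChanges:
    def _series(self, subject, values):
        return [make_sample(subject=subject, timepoint=tp, ref={"ci": r}, test={"ci": t})
                for tp, (r, t) in values.items()]

    def test_consecutive_deltas(self):
        samples = self._series("S1", {
            Timepoint.BASELINE: (4.0, 4.0),
            Timepoint.ROSC15: (3.0, 3.2),
            Timepoint.ROSC30: (3.5, 3.4),
        })
        deltas = consecutive_changes(samples)
        assert [(d.delta_ref, d.delta_test) for d in deltas] == [
            (pytest.approx(-1.0), pytest.approx(-0.8)),
            (pytest.approx(0.5), pytest.approx(0.2)),
        ]

    def test_baseline_only_contributes_nothing(self):
        samples = self._series("S1", {Timepoint.BASELINE: (4.0, 4.0)})
        assert consecutive_changes(samples) == []

    def test_gap_is_bridged(self):
        samples = self._series("S1", {
            Timepoint.BASELINE: (4.0, 4.1),
            Timepoint.ROSC30: (3.0, 3.1),
        })
        deltas = consecutive_changes(samples)
        assert len(deltas) == 1
        assert deltas[0].from_timepoint is Timepoint.BASELINE
        assert deltas[0].to_timepoint is Timepoint.ROSC30
        assert deltas[0].delta_ref == pytest.approx(-1.0)

    def test_flagged_samples_are_ignored(self):
        from coagree import QcFlag
        samples = self._series("S1", {
            Timepoint.BASELINE: (4.0, 4.0),
            Timepoint.ROSC15: (3.0, 3.0),
        })
        flagged = [make_sample(subject="S1", timepoint=Timepoint.ROSC15,
                               flags={QcFlag.SBP_DISCREPANCY})]
        assert consecutive_changes(samples[:1] + flagged) == []


class TestPolarTransform:
    def test_identity_line(self):
        point = polar_transform(dp(1.0, 1.0))
        assert point.angle_deg == pytest.approx(0.0)
        assert point.radius == pytest.approx(1.0)

    def test_half_circle_reflection(self):
        point = polar_transform(dp(-1.0, -1.0))
        assert point.angle_deg == pytest.approx(0.0)
        assert point.radius == pytest.approx(1.0)

    def test_hand_trigonometry(self):
        point = polar_transform(dp(2.0, 1.0))
        assert point.angle_deg == pytest.approx(-18.43, abs=0.01)
        assert point.radius == pytest.approx(1.5)

    def test_discordant_null_mean_change_is_excluded(self):
        point = polar_transform(dp(1.0, -1.0), threshold=0.45)
        assert point.radius == 0.0
        assert not point.included

    def test_zero_delta_convention(self):
        point = polar_transform(dp(0.0, 0.0))
        assert point.angle_deg == 0.0 and point.radius == 0.0 and not point.included

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(delta_values, delta_values)
    def test_matches_rotation_oracle(self, delta_ref, delta_test):
        point = polar_transform(dp(delta_ref, delta_test))
        if delta_ref == 0.0 and delta_test == 0.0:
            return
        angle, radius = rotation_oracle(delta_ref, delta_test)
        assert point.angle_deg == pytest.approx(angle, abs=1e-9)
        assert point.radius == pytest.approx(radius, abs=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(delta_values, delta_values)
    def test_reflection_invariance(self, delta_ref, delta_test):
        forward = polar_transform(dp(delta_ref, delta_test))
        reflected = polar_transform(dp(-delta_ref, -delta_test))
        assert reflected.angle_deg == pytest.approx(forward.angle_deg, abs=1e-9)
        assert reflected.radius == pytest.approx(forward.radius, abs=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(delta_values, delta_values)
    def test_method_swap_negates_angle(self, delta_ref, delta_test):
        forward = polar_transform(dp(delta_ref, delta_test))
        swapped = polar_transform(dp(delta_test, delta_ref))
        assert swapped.radius == pytest.approx(forward.radius, abs=1e-12)
        if abs(abs(forward.angle_deg) - 90.0) < 1e-9:
            assert abs(swapped.angle_deg) == pytest.approx(90.0, abs=1e-9)
        else:
            assert swapped.angle_deg == pytest.approx(-forward.angle_deg, abs=1e-9)


class TestExclusionThreshold:
    def test_fraction_of_reference_mean(self):
        assert exclusion_threshold_from_mean(4.5, 0.10) == pytest.approx(0.45)

    def test_fraction_zero_excludes_only_zero_radius(self):
        samples = [make_sample(subject=f"S{i}") for i in range(3)]
        assert exclusion_threshold(samples, fraction=0.0) == 0.0
        included = polar_transform(dp(0.3, 0.2), threshold=0.0)
        assert included.included
        zero = polar_transform(dp(1.0, -1.0), threshold=0.0)
        assert not zero.included

    def test_override_wins(self):
        samples = [make_sample(subject=f"S{i}") for i in range(3)]
        assert exclusion_threshold(samples, override=1.0) == 1.0

    def test_boundary_radius_is_included(self):
        point = polar_transform(dp(0.45, 0.45), threshold=0.45)
        assert point.included


class TestPolarStatistics:
    def _points(self, angles):
        return [polar_transform(dp(1.0, math.tan(math.radians(a + 45.0)) * 1.0))
                for a in angles]

    def test_hand_example(self):
        points = self._points([0.0, 20.0, -40.0])
        result = polar_statistics(points)
        assert result.mean_angular_deviation == pytest.approx(-6.67, abs=0.01)
        assert result.concordance_pct == pytest.approx(66.7, abs=0.05)
        assert not result.good_trending

    def test_all_on_axis_is_good(self):
        result = polar_statistics(self._points([0.0, 0.0, 0.0]))
        assert result.mean_angular_deviation == pytest.approx(0.0)
        assert result.concordance_pct == 100.0
        assert result.good_trending

    def test_boundary_is_strict_above_limit(self):
        result = polar_statistics(self._points([31.0]))
        assert result.concordance_pct == 0.0
        result = polar_statistics(self._points([30.0]))
        assert result.concordance_pct == 100.0

    def test_no_included_points_reports_counts_only(self):
        points = [polar_transform(dp(0.1, 0.1), threshold=10.0)]
        result = polar_statistics(points, exclusion_threshold=10.0)
        assert result.n_excluded == 1 and not result.available
        assert result.mean_angular_deviation is None


class TestTrendAnalysis:
    def test_perfect_trending(self):
        samples = []
        for i, values in enumerate([(4.0, 3.0, 3.5, 4.2), (5.0, 3.5, 4.0, 4.8)]):
            for tp, v in zip(Timepoint, values):
                samples.append(make_sample(subject=f"S{i}", timepoint=tp,
                                           ref={"ci": v}, test={"ci": v}))
        result = TrendAnalysis(samples).fit()
        assert result.concordance_pct == 100.0
        assert result.mean_angular_deviation == pytest.approx(0.0)
        assert result.good_trending
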