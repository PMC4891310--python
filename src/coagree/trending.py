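"""Polar-plot trending analysis of consecutive cardiac-index changes.

A monitor that tracks *changes* well may still be biased in level, so
trending is assessed separately from agreement: for every subject, the
change in the variable between consecutive available time points is
computed for each monitor, giving a vector (delta_ref, delta_test) per
transition.  Each vector is mapped to a half-circle polar point:

* the mean change s = (delta_ref + delta_test)/2 orients the point — if
  s < 0 both deltas are negated (180 degree reflection onto the right
  half-plane, the standard half-circle convention) and the radius is
  |s|;
* the angle is the deviation of the vector from the 45 degree identity
  line (0 degrees = perfect concurrence), confined to (-90, +90];
* points whose radius falls below an exclusion threshold — by default
  10 % of the overall reference-method mean — are too small to carry
  trend information and are excluded (a zero radius is always
  excluded).

Good trending requires >= 95 % of included points within +/-30 degrees
of the polar axis; the mean (signed, arithmetic) angular deviation is
reported alongside the concordance rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import PairedSample, Timepoint, TIMEPOINT_ORDER
from .exceptions import InsufficientDataError

_ANGLE_EPS = 1e-12


@dataclass(frozen=True)
class DeltaPair:
    """Consecutive change of one subject, per monitor."""

    subject_id: str
    from_timepoint: Timepoint
    to_timepoint: Timepoint
    delta_ref: float
    delta_test: float

    def __post_init__(self) -> None:
        if self.from_timepoint.order >= self.to_timepoint.order:
            raise ValueError("from_timepoint must precede to_timepoint")
        if not (math.isfinite(self.delta_ref) and math.isfinite(self.delta_test)):
            raise ValueError("deltas must be finite")


@dataclass(frozen=True)
class PolarPoint:
    source: DeltaPair
    angle_deg: float   # deviation from the polar (identity) axis, in (-90, +90]
    radius: float      # |mean change|, in the variable's units
    included: bool


@dataclass(frozen=True)
class TrendingResults:
    """Aggregated polar trending statistics."""

    variable: str
    n_deltas: int
    n_included: int
    n_excluded: int
    mean_angular_deviation: float | None
    concordance_pct: float | None
    good_trending: bool | None
    limit_deg: float
    exclusion_threshold: float
    points: tuple[PolarPoint, ...]

    @property
    def available(self) -> bool:
        return self.n_included > 0

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready table: one row per consecutive-change polar point."""
        rows = [{
            "subject_id": p.source.subject_id,
            "from_timepoint": p.source.from_timepoint.value,
            "to_timepoint": p.source.to_timepoint.value,
            "delta_ref": p.source.delta_ref,
            "delta_test": p.source.delta_test,
            "angle_deg": p.angle_deg,
            "radius": p.radius,
            "included": int(p.included),
        } for p in self.points]
        return pd.DataFrame(rows, columns=[
            "subject_id", "from_timepoint", "to_timepoint",
            "delta_ref", "delta_test", "angle_deg", "radius", "included",
        ])

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "n_deltas": self.n_deltas,
            "n_included": self.n_included,
            "n_excluded": self.n_excluded,
            "mean_angular_deviation": self.mean_angular_deviation,
            "concordance_pct": self.concordance_pct,
            "good_trending": None if self.good_trending is None else int(self.good_trending),
            "limit_deg": self.limit_deg,
            "exclusion_threshold": self.exclusion_threshold,
        }

    def summary(self) -> str:
        lines = [
            f"Polar trending analysis: {self.variable}",
            "-" * 50,
            f"consecutive changes      {self.n_deltas}",
            f"included / excluded      {self.n_included} / {self.n_excluded}"
            f"   (exclusion radius < {self.exclusion_threshold:.3g})",
        ]
        if self.available:
            lines += [
                f"mean angular deviation   {self.mean_angular_deviation:8.1f} deg",
                f"concordance (+/-{self.limit_deg:.0f} deg)  {self.concordance_pct:8.1f} %"
                + ("   good trending (>= 95 %)" if self.good_trending else "   poor trending (< 95 %)"),
            ]
        else:
            lines.append("no included points: statistics unavailable")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Half-circle polar scatter of the included and excluded points."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        for included, color in ((True, "C0"), (False, "0.7")):
            pts = [p for p in self.points if p.included is included]
            ax.scatter([math.radians(p.angle_deg) for p in pts],
                       [p.radius for p in pts], s=20, color=color,
                       label="included" if included else "excluded")
        for limit in (self.limit_deg, -self.limit_deg):
            ax.plot([math.radians(limit)] * 2, ax.get_ylim(), color="k", lw=0.8, ls="--")
        ax.set_thetamin(-90)
        ax.set_thetamax(90)
        ax.legend(loc="upper right")
        return ax


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def consecutive_changes(samples: Iterable[PairedSample], variable: str = "ci") -> list[DeltaPair]:
    """Per-subject changes between consecutive available time points.

    Gaps are bridged: a subject observed at baseline and 30 min only
    contributes the baseline -> 30 min transition.  Subjects with fewer
    than two QC-clean time points contribute nothing.
    """
    by_subject: dict[str, list[PairedSample]] = {}
    for sample in samples:
        if sample.is_clean:
            by_subject.setdefault(sample.subject_id, []).append(sample)

    deltas: list[DeltaPair] = []
    for subject in sorted(by_subject):
        series = sorted(by_subject[subject], key=lambda s: s.timepoint.order)
        for earlier, later in zip(series, series[1:]):
            r0, r1 = earlier.ref.get(variable), later.ref.get(variable)
            t0, t1 = earlier.test.get(variable), later.test.get(variable)
            if None in (r0, r1, t0, t1):
                continue
            deltas.append(DeltaPair(subject, earlier.timepoint, later.timepoint,
                                    r1 - r0, t1 - t0))
    return deltas


def polar_transform(delta: DeltaPair, threshold: float = 0.0) -> PolarPoint:
    """Map a change vector to its half-circle polar representation.

    The mean change s = (delta_ref + delta_test)/2 gives the radius
    |s|; when s < 0 both deltas are reflected through the origin so all
    points live in the half-plane of positive mean change.  The angle is
    the vector's direction minus 45 degrees (deviation from the identity
    line), confined to (-90, +90].  A zero-radius point carries no trend
    direction: it gets angle 0 when both deltas vanish and is always
    excluded.
    """
    d_ref, d_test = delta.delta_ref, delta.delta_test
    s = (d_ref + d_test) / 2.0
    if s < 0:
        d_ref, d_test, radius = -d_ref, -d_test, -s
    else:
        radius = s
    if d_ref == 0.0 and d_test == 0.0:
        angle = 0.0
    else:
        angle = math.degrees(math.atan2(d_test, d_ref)) - 45.0
        if angle <= -90.0 + _ANGLE_EPS:
            angle += 180.0
    included = radius > 0.0 and radius >= threshold
    return PolarPoint(delta, angle, radius, included)


def exclusion_threshold(samples: Iterable[PairedSample], variable: str = "ci",
                        fraction: float = 0.10,
                        override: float | None = None) -> float:
    """Central exclusion-zone radius: ``fraction`` of the reference mean.

    An explicit ``override`` (absolute, in the variable's units) wins
    over the fraction.  Raises on a non-positive reference mean.
    """
    if override is not None:
        return float(override)
    values = [s.ref.get(variable) for s in samples
              if s.is_clean and s.ref.get(variable) is not None]
    if not values:
        raise InsufficientDataError(f"no usable reference values for {variable!r}")
    return exclusion_threshold_from_mean(float(np.mean(values)), fraction)


def exclusion_threshold_from_mean(mean_ref: float, fraction: float = 0.10) -> float:
    """Exclusion radius from a known reference-method mean."""
    if mean_ref <= 0:
        raise ValueError(f"exclusion threshold undefined: non-positive mean {mean_ref}")
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    return fraction * mean_ref


def polar_statistics(points: Sequence[PolarPoint], limit_deg: float = 30.0,
                     variable: str = "ci",
                     exclusion_threshold: float = 0.0) -> TrendingResults:
    """Aggregate polar points into the trending statistics.

    Over included points: the arithmetic mean of the signed angles and
    the percentage with |angle| <= ``limit_deg`` (boundary inclusive);
    good trending requires that percentage to reach 95.  With no
    included points only the counts are reported.
    """
    points = tuple(points)
    included = [p for p in points if p.included]
    n_inc = len(included)
    if n_inc:
        angles = np.array([p.angle_deg for p in included])
        mean_dev = float(angles.mean())
        concordance = float(100.0 * np.mean(np.abs(angles) <= limit_deg))
        good = concordance >= 95.0
    else:
        mean_dev = concordance = good = None
    return TrendingResults(
        variable=variable, n_deltas=len(points), n_included=n_inc,
        n_excluded=len(points) - n_inc,
        mean_angular_deviation=mean_dev, concordance_pct=concordance,
        good_trending=good, limit_deg=limit_deg,
        exclusion_threshold=exclusion_threshold, points=points,
    )


class TrendAnalysis:
    """Trending model over a set of paired samples.

    ``fit()`` extracts consecutive changes, sizes the exclusion zone
    (``exclusion_fraction`` of the reference mean unless an absolute
    ``exclusion_threshold`` is given), polar-transforms every change and
    aggregates the statistics into a :class:`TrendingResults`.
    """

    def __init__(self, samples: Iterable[PairedSample], variable: str = "ci",
                 exclusion_fraction: float = 0.10,
                 exclusion_threshold: float | None = None,
                 limit_deg: float = 30.0):
        self.samples = list(samples)
        self.variable = variable
        self.exclusion_fraction = exclusion_fraction
        self.exclusion_threshold_override = exclusion_threshold
        self.limit_deg = limit_deg

    def fit(self) -> TrendingResults:
        threshold = exclusion_threshold(
            self.samples, self.variable,
            fraction=self.exclusion_fraction,
            override=self.exclusion_threshold_override,
        )
        deltas = consecutive_changes(self.samples, self.variable)
        points = [polar_transform(d, threshold=threshold) for d in deltas]
        return polar_statistics(points, limit_deg=self.limit_deg,
                                variable=self.variable,
                                exclusion_threshold=threshold)
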