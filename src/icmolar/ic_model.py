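"""Theoretical inhibitory-cascade (IC) model of lower-molar proportions.

Under the cascade, the size of each molar is set by the balance ``a``
between a mesenchymal activator and inhibition from the next-anterior
molar.  The effect accumulates along the row, giving relative occlusal
areas ``(1, a, 2a - 1)`` for m1, m2, m3.  Two testable predictions
follow:

* in the morphospace with axes ``x = m2/m1`` and ``y = m3/m1`` every
  taxon lies on the line ``y = 2x - 1``, and m2 is never strictly the
  largest or strictly the smallest molar;
* m2 occupies exactly one third of total molar occlusal area.

This module encodes the line, the region/trend classification of
morphospace points relative to it, and the m2-share test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "IC_SLOPE",
    "IC_INTERCEPT",
    "IC_M2_SHARE",
    "ICTheory",
    "CascadeParams",
    "RegionLabel",
    "TrendLabel",
    "RegionSummary",
    "ic_line",
    "cascade_sizes",
    "m2_share_of_a",
    "classify_region",
    "classify_trend",
    "region_summary",
    "m2_share_test",
]

#: Slope of the predicted morphospace line m3/m1 = 2 (m2/m1) - 1.
IC_SLOPE = 2.0
#: Intercept of the predicted line.
IC_INTERCEPT = -1.0
#: Predicted share of total molar area occupied by m2 (exactly one third).
IC_M2_SHARE = 1.0 / 3.0


@dataclass(frozen=True)
class ICTheory:
    """The fixed theoretical parameters of the cascade model."""

    slope: float = IC_SLOPE
    intercept: float = IC_INTERCEPT
    m2_share_predicted: float = IC_M2_SHARE


@dataclass(frozen=True)
class CascadeParams:
    """Activator/inhibitor balance ``a`` governing relative molar size.

    ``a = 1`` gives three equal molars; ``a > 1`` posteriorly increasing
    size; ``a < 1`` posteriorly decreasing, with m3 lost at ``a <= 0.5``.
    """

    a: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"activator/inhibitor balance must be >= 0, got {self.a}")


class RegionLabel(enum.Enum):
    """Position of a morphospace point relative to the predicted regions."""

    M2_INTERMEDIATE = "m2_intermediate"
    M2_LARGEST = "m2_largest"
    M2_SMALLEST = "m2_smallest"


class TrendLabel(enum.Enum):
    """Size trend along the tooth row for points in the predicted region."""

    DECREASING = "decreasing"
    INCREASING = "increasing"
    ALL_EQUAL = "all_equal"


def ic_line(x: float) -> float:
    """Predicted m3/m1 ratio for a given m2/m1 ratio: ``2x - 1``."""
    if x < 0:
        raise ValueError(f"m2/m1 ratio must be >= 0, got {x}")
    return IC_SLOPE * x + IC_INTERCEPT


def cascade_sizes(params: CascadeParams | float) -> tuple[float, float, float]:
    """Relative molar areas ``(1, a, max(0, 2a - 1))`` for balance ``a``.

    A computed size of zero means the tooth does not form (m3 is lost
    when ``a <= 0.5``).
    """
    a = params.a if isinstance(params, CascadeParams) else float(params)
    if a < 0:
        raise ValueError(f"activator/inhibitor balance must be >= 0, got {a}")
    return (1.0, a, max(0.0, 2.0 * a - 1.0))


def m2_share_of_a(a: float) -> float:
    """Share of total molar area occupied by m2 under the cascade.

    ``share(a) = a / (1 + a + max(0, 2a - 1))``; equal to 1/3 for every
    ``a >= 0.5`` (where all three molars are present), and ``a / (1 + a)``
    below one third once m3 is lost.
    """
    s1, s2, s3 = cascade_sizes(a)
    return s2 / (s1 + s2 + s3)


def classify_region(x: float, y: float, tol: float = 0.0) -> RegionLabel:
    """Classify a morphospace point into the cascade's three regions.

    ``M2_LARGEST`` (bottom-right: m2 strictly exceeds m1 and m3) and
    ``M2_SMALLEST`` (top-left) are the two regions the model forbids;
    everything else, including every boundary where two molars are equal,
    is ``M2_INTERMEDIATE`` because equal sizes are a permitted outcome.
    ``tol`` widens the predicted region symmetrically.
    """
    if x <= 0 or y <= 0:
        raise ValueError(f"area ratios must be positive, got ({x}, {y})")
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    # x > 1 means m2 > m1; y < x means m3 < m2.
    if x > 1.0 + tol and y < x - tol:
        return RegionLabel.M2_LARGEST
    if x < 1.0 - tol and y > x + tol:
        return RegionLabel.M2_SMALLEST
    return RegionLabel.M2_INTERMEDIATE


def classify_trend(x: float, y: float, tol: float = 0.0) -> TrendLabel:
    """Size trend for a point in the predicted (m2-intermediate) region.

    DECREASING means m1 > m2 > m3, INCREASING m1 < m2 < m3; anything
    involving an equality within ``tol`` is ALL_EQUAL.
    """
    if classify_region(x, y, tol) is not RegionLabel.M2_INTERMEDIATE:
        raise ValueError(
            f"trend is defined only inside the predicted region, got ({x}, {y})"
        )
    if x < 1.0 - tol and y < x - tol:
        return TrendLabel.DECREASING
    if x > 1.0 + tol and y > x + tol:
        return TrendLabel.INCREASING
    return TrendLabel.ALL_EQUAL


@dataclass(frozen=True)
class RegionSummary:
    """Counts of genera per morphospace region and trend."""

    n: int
    region_counts: dict
    trend_counts: dict
    percent_predicted: float


def region_summary(
    points: Iterable[tuple[float, float]], tol: float = 0.0
) -> RegionSummary:
    """Count region and trend membership over morphospace points.

    ``points`` is an iterable of ``(x, y)`` ratio pairs (one per genus).
    The trend tally covers only points in the predicted region.  The
    headline percentage is ``100 * intermediate / n``.
    """
    region_counts = {label: 0 for label in RegionLabel}
    trend_counts = {label: 0 for label in TrendLabel}
    n = 0
    for x, y in points:
        n += 1
        region = classify_region(x, y, tol)
        region_counts[region] += 1
        if region is RegionLabel.M2_INTERMEDIATE:
            trend_counts[classify_trend(x, y, tol)] += 1
    if n == 0:
        raise ValueError("region_summary requires at least one point")
    pct = 100.0 * region_counts[RegionLabel.M2_INTERMEDIATE] / n
    return RegionSummary(
        n=n,
        region_counts=region_counts,
        trend_counts=trend_counts,
        percent_predicted=pct,
    )


def m2_share_test(shares: Sequence[float]):
    """Two-tailed one-sample t-test of m2 shares (in %) against 100/3.

    ``shares`` are per-genus mean m2 shares expressed as percentages of
    total molar area.  The reference value is the exact prediction
    100/3 %, not a rounded 33 or 33.33.
    """
    from .resampling_stats import one_sample_t

    if len(shares) < 2:
        raise ValueError("m2-share test requires at least two genera")
    return one_sample_t(shares, mu=100.0 / 3.0)
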