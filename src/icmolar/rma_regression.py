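"""Reduced major axis (standardized major axis) regression.

RMA is the symmetric line fit used throughout the molar-proportion
literature: both the m2/m1 and m3/m1 ratios carry measurement error, so
regressing one on the other by least squares would attenuate the slope.
The RMA slope is ``sign(r) * s_y / s_x`` and the intercept passes the
line through the centroid.

Confidence intervals come either from the standard analytic SMA interval
(the one allometry packages such as smatr report) or from a case
bootstrap.  Fitted lines are compared with each other, or with the
theoretical cascade line (slope 2, intercept -1), by 95% CI overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .ic_model import ICTheory

__all__ = [
    "RMAFit",
    "LineComparison",
    "PUBLISHED_FITS",
    "fit_rma",
    "rma_ci_analytic",
    "rma_ci_bootstrap",
    "compare_lines",
]


@dataclass(frozen=True)
class RMAFit:
    """A fitted RMA line, optionally with confidence intervals."""

    n: int
    slope: float
    intercept: float
    r: float
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None
    alpha: float = 0.05
    method: str | None = None
    degenerate_ci: bool = False  # r^2 == 1: intervals collapse to a point
    source: str = "fit"


@dataclass(frozen=True)
class LineComparison:
    """CI-overlap comparison of two lines' slopes and intercepts."""

    slope_overlap: bool
    intercept_overlap: bool
    different: bool


#: Published regression rows for the comparison table: previously
#: reported fits for murine rodents, arvicoline rodents, and canids.
#: These are literature constants, not recomputed here.
PUBLISHED_FITS = {
    "murine": RMAFit(
        n=29, slope=2.150, intercept=-1.219, r=np.nan,
        slope_ci=(1.772, 2.688), intercept_ci=(-1.651, -0.925),
        method="published", source="murine rodents",
    ),
    "arvicoline": RMAFit(
        n=-1, slope=1.390, intercept=-0.313, r=np.nan,
        slope_ci=(1.208, 1.555), intercept_ci=(-0.407, -0.213),
        method="published", source="arvicoline rodents",
    ),
    "canid": RMAFit(
        n=-1, slope=0.450, intercept=-0.080, r=np.nan,
        slope_ci=(0.376, 0.515), intercept_ci=(-0.104, -0.037),
        method="published", source="Canidae",
    ),
}


def _as_xy(points: Sequence[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def fit_rma(points: Sequence[Sequence[float]]) -> RMAFit:
    """Point estimates of the RMA slope and intercept.

    slope = sign(r) * s_y / s_x (sample standard deviations, n-1
    denominator, which cancels in the ratio); intercept = ybar - slope * xbar.
    """
    x, y = _as_xy(points)
    n = x.size
    if n < 3:
        raise ValueError(f"RMA requires n >= 3, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("RMA undefined when x or y has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return RMAFit(n=n, slope=float(slope), intercept=intercept, r=r)


def rma_ci_analytic(
    points: Sequence[Sequence[float]], alpha: float = 0.05
) -> RMAFit:
    """RMA fit with the standard analytic SMA confidence intervals.

    The slope interval is ``[b (sqrt(B+1) - sqrt(B)), b (sqrt(B+1) + sqrt(B))]``
    with ``B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2)``.  The intercept
    interval propagates the slope endpoints through
    ``intercept = ybar - b * xbar`` and adds the t-interval uncertainty
    of ``ybar`` in quadrature.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    fit = fit_rma(points)
    x, y = _as_xy(points)
    n = fit.n
    r2 = fit.r**2
    b = fit.slope
    if r2 >= 1.0:
        return replace(
            fit,
            slope_ci=(b, b),
            intercept_ci=(fit.intercept, fit.intercept),
            alpha=alpha,
            method="analytic",
            degenerate_ci=True,
        )
    big_b = stats.f.ppf(1.0 - alpha, 1, n - 2) * (1.0 - r2) / (n - 2)
    lo = b * (np.sqrt(big_b + 1.0) - np.sqrt(big_b))
    hi = b * (np.sqrt(big_b + 1.0) + np.sqrt(big_b))
    slope_ci = (float(min(lo, hi)), float(max(lo, hi)))
    # Intercept: slope uncertainty through the centroid plus the
    # standard error of ybar, combined in quadrature.
    xbar, ybar = x.mean(), y.mean()
    half_slope = (slope_ci[1] - slope_ci[0]) / 2.0
    se_ybar = y.std(ddof=1) / np.sqrt(n) * stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    half_int = float(np.hypot(half_slope * xbar, se_ybar))
    intercept_ci = (fit.intercept - half_int, fit.intercept + half_int)
    return replace(
        fit,
        slope_ci=slope_ci,
        intercept_ci=intercept_ci,
        alpha=alpha,
        method="analytic",
    )


def rma_ci_bootstrap(
    points: Sequence[Sequence[float]],
    alpha: float = 0.05,
    reps: int = 1999,
    seed: int = 0,
    max_retries: int = 100,
) -> RMAFit:
    """RMA fit with percentile case-bootstrap confidence intervals.

    Specimens (rows) are resampled with replacement ``reps`` times and
    the line refitted; degenerate resamples with zero variance are
    redrawn up to ``max_retries`` times.  Deterministic given ``seed``.
    """
    if reps < 999:
        raise ValueError("use at least 999 bootstrap replicates")
    fit = fit_rma(points)
    arr = np.asarray(points, dtype=float)
    n = arr.shape[0]
    rng = np.random.default_rng(seed)
    slopes = np.empty(reps)
    intercepts = np.empty(reps)
    for i in range(reps):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            sample = arr[idx]
            if sample[:, 0].std() > 0 and sample[:, 1].std() > 0:
                break
        else:
            raise RuntimeError("bootstrap resampling kept producing zero variance")
        bfit = fit_rma(sample)
        slopes[i] = bfit.slope
        intercepts[i] = bfit.intercept
    qs = (100.0 * alpha / 2.0, 100.0 * (1.0 - alpha / 2.0))
    s_lo, s_hi = np.percentile(slopes, qs)
    i_lo, i_hi = np.percentile(intercepts, qs)
    return replace(
        fit,
        slope_ci=(float(s_lo), float(s_hi)),
        intercept_ci=(float(i_lo), float(i_hi)),
        alpha=alpha,
        method="bootstrap",
    )


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_lines(a: RMAFit, b: "RMAFit | ICTheory") -> LineComparison:
    """Compare two lines by 95% CI overlap.

    ``b`` may be a theoretical line (e.g. the cascade's slope 2,
    intercept -1), treated as zero-width intervals, so the test reduces
    to containment in ``a``'s intervals.  ``different`` is True iff
    either parameter's intervals are disjoint.
    """
    if a.slope_ci is None or a.intercept_ci is None:
        raise ValueError("first line has no confidence intervals")
    if isinstance(b, ICTheory):
        b_slope_ci = (b.slope, b.slope)
        b_int_ci = (b.intercept, b.intercept)
    else:
        if b.slope_ci is None or b.intercept_ci is None:
            raise ValueError("second line has no confidence intervals")
        b_slope_ci = b.slope_ci
        b_int_ci = b.intercept_ci
    slope_overlap = _intervals_overlap(a.slope_ci, b_slope_ci)
    intercept_overlap = _intervals_overlap(a.intercept_ci, b_int_ci)
    return LineComparison(
        slope_overlap=slope_overlap,
        intercept_overlap=intercept_overlap,
        different=not (slope_overlap and intercept_overlap),
    )
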