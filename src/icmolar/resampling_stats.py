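"""Rank correlation, one-sample t-test, and one-way PERMANOVA.

These are the three inferential procedures the molar-proportion pipeline
relies on, implemented directly so that every statistic the report
prints (including the Spearman S statistic and the PERMANOVA
sum-of-squares partition) is defined in one place.  Independent
implementations (scipy, scikit-bio, vegan::adonis) serve as
cross-checks in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "PermanovaResult",
    "spearman_rank",
    "one_sample_t",
    "permanova_one_way",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with the classical S statistic.

    Without ties ``rho = 1 - 6 S / (n^3 - n)`` exactly, with
    ``S = sum of squared rank differences``; with ties S is derived from
    rho through the same identity so printed values match standard
    statistical output.
    """

    n: int
    rho: float
    S: float
    p: float


@dataclass(frozen=True)
class TTestResult:
    """One-sample two-tailed t-test result with a 95% CI on the mean."""

    t: float
    df: int
    mean: float
    ci: tuple[float, float]
    p: float


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA table for a single grouping factor."""

    term: str
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    ms_between: float
    ms_within: float
    F: float
    R2: float
    p: float
    n_perm: int
    seed: int


def spearman_rank(xs: Sequence[float], ys: Sequence[float]) -> CorrelationResult:
    """Tie-aware Spearman rank correlation.

    Midranks are assigned to ties; rho is the Pearson correlation of the
    two rank vectors; the p-value comes from the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2`` df,
    two-tailed.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    rx = stats.rankdata(x)  # midranks for ties
    ry = stats.rankdata(y)
    if np.array_equal(rx, ry):  # perfect concordance: rho exactly 1, S = 0
        rho = 1.0
    elif np.array_equal(rx, n + 1 - ry):
        rho = -1.0
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
        rho = min(1.0, max(-1.0, rho))
    S = (1.0 - rho) * (n**3 - n) / 6.0
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(n=n, rho=rho, S=float(S), p=p)


def one_sample_t(values: Sequence[float], mu: float) -> TTestResult:
    """Two-tailed one-sample Student's t-test of the mean against ``mu``.

    The 95% CI on the mean is ``mean +/- t(0.975, n-1) * s / sqrt(n)``
    regardless of the tested ``mu``.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    mean = float(v.mean())
    s = float(v.std(ddof=1))
    df = n - 1
    half = float(stats.t.ppf(0.975, df)) * s / np.sqrt(n)
    ci = (mean - half, mean + half)
    if s == 0.0:
        if mean == mu:
            return TTestResult(t=0.0, df=df, mean=mean, ci=ci, p=1.0)
        t_stat = np.inf if mean > mu else -np.inf
        return TTestResult(t=float(t_stat), df=df, mean=mean, ci=ci, p=0.0)
    t_stat = (mean - mu) / (s / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t_stat), df=df))
    return TTestResult(t=float(t_stat), df=df, mean=mean, ci=ci, p=p)


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Within-group sum of squares from a squared-distance matrix."""
    total = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ng = idx.size
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * ng)  # full matrix counts each pair twice
    return total


def permanova_one_way(
    coords: Sequence[Sequence[float]],
    labels: Sequence,
    distance: str = "euclidean",
    n_perm: int = 999,
    seed: int = 0,
    term: str = "group",
) -> PermanovaResult:
    """One-way permutational MANOVA (Anderson's pseudo-F by relabelling).

    With squared pairwise distances d2_ij the partition is

        ss_total  = sum_{i<j} d2_ij / n
        ss_within = sum_g sum_{i<j in g} d2_ij / n_g
        ss_between = ss_total - ss_within

    with ``df_between = a - 1`` and ``df_within = n - a`` for ``a``
    groups.  The p-value is ``(#{F_perm >= F_obs} + 1) / (n_perm + 1)``
    over uniformly random relabellings, deterministic given ``seed``.
    """
    if distance != "euclidean":
        raise ValueError(f"unsupported distance: {distance!r}")
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives an unstable p-value")
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    lab = np.asarray(labels)
    n = pts.shape[0]
    if lab.size != n:
        raise ValueError("coords and labels must have equal length")
    groups = np.unique(lab)
    a = groups.size
    if a < 2:
        raise ValueError("need at least two groups")
    if a == n:
        raise ValueError("every point in its own group leaves no within-group df")

    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    ss_total = float(d2.sum() / (2.0 * n))
    ss_within = _ss_within(d2, lab, groups)
    ss_between = ss_total - ss_within
    df_between = a - 1
    df_within = n - a
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    # Perfect separation (zero within-group scatter) gives an infinite
    # pseudo-F rather than a division error.
    f_obs = ms_between / ms_within if ms_within > 0 else math.inf
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm_lab = lab[rng.permutation(n)]
        ss_w = _ss_within(d2, perm_lab, groups)
        if ss_w > 0:
            f_perm = ((ss_total - ss_w) / df_between) / (ss_w / df_within)
        else:
            f_perm = math.inf
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    return PermanovaResult(
        term=term,
        df_between=df_between,
        df_within=df_within,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_total,
        ms_between=ms_between,
        ms_within=ms_within,
        F=float(f_obs),
        R2=float(r2),
        p=float(p),
        n_perm=n_perm,
        seed=seed,
    )
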