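"""Nonstationarity diagnostics for RR-interval series.

Two complementary tests:

Heuristic segmentation
    Recursively split the series at the point maximizing a pooled-variance
    t-statistic between the left and right means; a split is accepted when
    its significance, estimated by the Bernaola-Galvan approximation

        P(t_max) ~ [1 - I_{nu/(nu + t²)}(delta·nu, delta)]^eta,
        nu = n - 2, eta = 4.19 ln(n) - 11.54, delta = 0.40,

    exceeds a threshold (default 0.95) and both resulting segments keep the
    minimum length (default 40 intervals, i.e. roughly the VLF/LF boundary
    at normal heart rates).  A series is stationary iff it is never split.

Restricted weak stationarity (RWS) test
    Draw 8 random subsequences of 50 intervals and test whether their means
    (Kruskal-Wallis) and dispersions (Brown-Forsythe, i.e. Levene on
    medians) are compatible; a stationary series should give p > 0.05 on
    both.  Subsequences may overlap: with typical 5-min window lengths
    (roughly 340-480 intervals) eight disjoint windows of 50 are often
    impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .rr_core import EmptySeriesError

#: Sentinel t-value for a split with zero pooled variance but unequal means.
T_CAP = 1e6


@dataclass(frozen=True)
class SegmentationResult:
    """Output of heuristic segmentation.

    ``change_points[i]`` is the 0-based index of the first sample of the
    (i+1)-th segment; a stationary verdict is exactly ``n_segments == 1``.
    """

    change_points: tuple[int, ...]
    segment_medians: tuple[float, ...]
    min_len: int
    significance_level: float

    @property
    def n_segments(self) -> int:
        return len(self.change_points) + 1

    @property
    def stationary(self) -> bool:
        return self.n_segments == 1


@dataclass(frozen=True)
class RWSResult:
    """Probabilities of equal subsequence means/variances; stationary iff both > alpha."""

    p_mean: float
    p_var: float
    n_sub: int
    sub_len: int
    seed: int | None = None
    alpha: float = 0.05

    @property
    def stationary(self) -> bool:
        return self.p_mean > self.alpha and self.p_var > self.alpha


def split_statistic(x: np.ndarray, i: int) -> float:
    """Two-sample t-value for splitting ``x`` before index ``i``.

    t = |mean(left) - mean(right)| / (s_pooled * sqrt(1/n_l + 1/n_r)).
    Degenerate cases: zero pooled variance gives 0 for equal means and a
    capped sentinel (treated as maximally significant) for unequal means.
    """
    x = np.asarray(x, dtype=float)
    left, right = x[:i], x[i:]
    if left.size < 2 or right.size < 2:
        raise ValueError("both sides of a split need at least 2 points")
    dmean = abs(left.mean() - right.mean())
    ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
    pooled_var = ss / (left.size + right.size - 2)
    if pooled_var == 0:
        return 0.0 if dmean == 0 else T_CAP
    s_d = np.sqrt(pooled_var * (1.0 / left.size + 1.0 / right.size))
    return float(dmean / s_d)


def _split_t_profile(x: np.ndarray, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    """t(i) for all admissible splits (both sides >= min_len), vectorized."""
    n = x.size
    splits = np.arange(max(min_len, 2), min(n - min_len, n - 2) + 1)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    nl = splits.astype(float)
    nr = n - nl
    sum_l = csum[splits - 1]
    sum_r = csum[-1] - sum_l
    mean_l = sum_l / nl
    mean_r = sum_r / nr
    ss_l = csq[splits - 1] - nl * mean_l**2
    ss_r = (csq[-1] - csq[splits - 1]) - nr * mean_r**2
    pooled = (ss_l + ss_r) / (n - 2)
    dmean = np.abs(mean_l - mean_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dmean / np.sqrt(pooled * (1.0 / nl + 1.0 / nr))
    t = np.where(pooled <= 0, np.where(dmean > 0, T_CAP, 0.0), t)
    # guard tiny negative ss from cancellation
    t = np.nan_to_num(t, nan=0.0, posinf=T_CAP)
    return splits, t


def split_significance(t_max: float, n: int, delta: float = 0.40) -> float:
    """Approximate P(max-t over all splits <= t_max) for an i.i.d. series."""
    nu = n - 2
    eta = 4.19 * np.log(n) - 11.54
    p_single = 1.0 - special.betainc(delta * nu, delta, nu / (nu + t_max**2))
    return float(p_single**eta)


def segment(
    x: np.ndarray,
    min_len: int = 40,
    significance_level: float = 0.95,
) -> SegmentationResult:
    """Recursive heuristic segmentation into approximately stationary pieces.

    Series shorter than ``2 * min_len`` admit no split and come back as a
    single segment (stationary by construction).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise EmptySeriesError("segmentation needs at least 2 samples")

    change_points: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        n = seg.size
        if n < 2 * min_len:
            return
        splits, t = _split_t_profile(seg, min_len)
        if splits.size == 0:
            return
        best = int(np.argmax(t))
        if split_significance(float(t[best]), n) >= significance_level:
            cut = lo + int(splits[best])
            change_points.append(cut)
            recurse(lo, cut)
            recurse(cut, hi)

    recurse(0, x.size)
    cps = tuple(sorted(change_points))
    bounds = (0, *cps, x.size)
    medians = tuple(
        float(np.median(x[a:b])) for a, b in zip(bounds[:-1], bounds[1:])
    )
    return SegmentationResult(
        change_points=cps,
        segment_medians=medians,
        min_len=min_len,
        significance_level=significance_level,
    )


def rws_test(
    x: np.ndarray,
    n_sub: int = 8,
    sub_len: int = 50,
    seed: int | np.random.Generator | None = None,
    method: str = "rank",
) -> RWSResult:
    """Restricted weak stationarity test on random subsequences.

    ``method="rank"`` (default) uses Kruskal-Wallis for location and
    Brown-Forsythe (Levene on medians) for dispersion; ``method="parametric"``
    uses one-way ANOVA and Bartlett.  Start indices are drawn uniformly
    without replacement; overlap between subsequences is permitted.
    """
    x = np.asarray(x, dtype=float)
    if x.size < sub_len:
        raise EmptySeriesError(
            f"series length {x.size} shorter than subsequence length {sub_len}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_starts = x.size - sub_len + 1
    if n_starts < n_sub:
        raise EmptySeriesError(
            f"only {n_starts} possible subsequence starts for n_sub={n_sub}"
        )
    starts = rng.choice(n_starts, size=n_sub, replace=False)
    groups = [x[s : s + sub_len] for s in starts]

    if np.ptp(x) == 0:
        p_mean = p_var = 1.0
    elif method == "rank":
        p_mean = _safe_p(stats.kruskal, groups)
        p_var = _safe_p(stats.levene, groups, center="median")
    elif method == "parametric":
        p_mean = _safe_p(stats.f_oneway, groups)
        p_var = _safe_p(stats.bartlett, groups)
    else:
        raise ValueError(f"unknown method {method!r}")

    return RWSResult(
        p_mean=p_mean,
        p_var=p_var,
        n_sub=n_sub,
        sub_len=sub_len,
        seed=seed if isinstance(seed, int) else None,
    )


def _safe_p(test, groups, **kwargs) -> float:
    """Run a scipy k-sample test, mapping degenerate inputs to p = 1."""
    try:
        return float(test(*groups, **kwargs).pvalue)
    except ValueError:
        return 1.0
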