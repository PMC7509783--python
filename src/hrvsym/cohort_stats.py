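"""Nonparametric repeated-measures statistics across the nine periods.

The cohort layer works on subjects x periods matrices of one HRV parameter
(missing cells allowed).  Period effects are tested with the Friedman rank
test (complete cases) or the Skillings-Mack generalization when observations
are missing; significant omnibus results are followed by pairwise Wilcoxon
signed-rank tests with Holm step-down adjustment.  Gender contrasts use the
Mann-Whitney U test.  All tests are rank-based, so any strictly monotone
transform of the parameter (e.g. the natural logarithm applied to the skewed
spectral powers) leaves the omnibus results unchanged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass(frozen=True)
class CohortMatrix:
    """Subjects x periods values of one parameter; NaN marks missing."""

    values: pd.DataFrame  # index = subject ids, columns = period labels
    parameter_name: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[1] < 2:
            raise ValueError("need at least 2 periods")
        observed_per_subject = v.notna().sum(axis=1)
        if (observed_per_subject >= 2).sum() < 2:
            raise ValueError("need >= 2 subjects with >= 2 observed periods")

    @property
    def period_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    def complete_rows(self) -> pd.DataFrame:
        return self.values.dropna(axis=0)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    method: str


@dataclass(frozen=True)
class PairResult:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float
    testable: bool = True


@dataclass(frozen=True)
class PosthocResult:
    pairs: tuple[PairResult, ...]
    method: str
    note: str = ""

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [p.pair for p in self.pairs if p.testable and p.adjusted_p < ALPHA]


def describe(values) -> tuple[float, float, float]:
    """Median and interquartile bounds (linear-interpolation percentiles).

    Returns ``(median, q25, q75)``; all NaN for an empty/all-missing input.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (float("nan"),) * 3
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    return float(med), float(q25), float(q75)


def friedman(m: CohortMatrix) -> TestResult:
    """Friedman chi-square test on complete cases, with mid-rank tie correction.

    chi2 = [12n/(k(k+1))] * sum_j (Rbar_j - (k+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(n k (k^2 - 1)).
    """
    data = m.complete_rows().to_numpy(dtype=float)
    n, k = data.shape
    if n < 2:
        raise ValueError(
            "fewer than 2 complete rows; use skillings_mack for missing data"
        )
    if k < 3:
        raise ValueError("Friedman test needs at least 3 periods")

    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rbar = ranks.mean(axis=0)
    statistic = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)

    # tie correction: per row, sum over tie groups of (t^3 - t)
    tie_sum = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:  # all values tied in every row
        return TestResult(0.0, k - 1, 1.0, "friedman")
    statistic /= correction

    p = float(stats.chi2.sf(statistic, k - 1))
    return TestResult(float(statistic), k - 1, p, "friedman")


def skillings_mack(m: CohortMatrix) -> TestResult:
    """Skillings-Mack test: Friedman-type rank test tolerating missing cells.

    Per subject, the observed values are mid-ranked, centered at (s+1)/2 and
    weighted by sqrt(12/(s+1)) (s = number observed).  The weighted centered
    ranks are summed per period into the vector A; the statistic is
    A' Sigma^- A with Sigma the null covariance implied by the observation
    pattern (Sigma_jj = sum over subjects observing j of (s_i - 1),
    Sigma_jk = -#{subjects observing both j and k}) and a Moore-Penrose
    pseudoinverse; df = rank(Sigma).  On complete data the statistic equals
    the (untied) Friedman chi-square exactly.
    """
    data = m.values.to_numpy(dtype=float)
    n, k = data.shape
    observed = np.isfinite(data)
    if not observed.any(axis=0).all():
        empty = [m.period_labels[j] for j in np.flatnonzero(~observed.any(axis=0))]
        raise ValueError(f"periods never observed: {empty}")
    _check_connected(observed, m.period_labels)

    a = np.zeros(k)
    sigma = np.zeros((k, k))
    for i in range(n):
        obs = observed[i]
        s = int(obs.sum())
        if s < 2:
            continue  # a singly-observed subject carries no rank information
        ranks = stats.rankdata(data[i, obs])
        w = np.sqrt(12.0 / (s + 1))
        a[obs] += w * (ranks - (s + 1) / 2.0)
        # null covariance of the weighted centered ranks for this subject
        block = np.full((s, s), -1.0)
        np.fill_diagonal(block, s - 1.0)
        idx = np.flatnonzero(obs)
        sigma[np.ix_(idx, idx)] += block

    sigma_pinv = np.linalg.pinv(sigma)
    statistic = float(a @ sigma_pinv @ a)
    df = int(np.linalg.matrix_rank(sigma))
    p = float(stats.chi2.sf(statistic, df))
    return TestResult(statistic, df, p, "skillings-mack")


def _check_connected(observed: np.ndarray, labels: list[str]) -> None:
    """Periods must be linked through co-observed subjects for Sigma^- to be valid."""
    k = observed.shape[1]
    adj = np.zeros((k, k), dtype=bool)
    for row in observed:
        idx = np.flatnonzero(row)
        adj[np.ix_(idx, idx)] = True
    reach = {0}
    frontier = {0}
    while frontier:
        nxt = set()
        for j in frontier:
            nxt |= set(np.flatnonzero(adj[j]))
        frontier = nxt - reach
        reach |= nxt
    if len(reach) < k:
        blocks = sorted(set(range(k)) - reach)
        raise ValueError(
            f"observation pattern disconnected: periods "
            f"{[labels[j] for j in blocks]} share no subjects with {labels[0]}"
        )


def posthoc(
    m: CohortMatrix,
    omnibus: TestResult,
    method: str = "wilcoxon-holm",
    alpha: float = ALPHA,
) -> PosthocResult:
    """Pairwise period comparisons, gated on a significant omnibus test.

    Default: exact/mid-rank Wilcoxon signed-rank per period pair with Holm
    step-down adjustment over all pairs.  Alternative
    ``method="siegel-castellan"``: critical-difference comparison of Friedman
    mean ranks with a Bonferroni-adjusted normal quantile.
    """
    labels = m.period_labels
    all_pairs = list(itertools.combinations(labels, 2))
    if omnibus.p >= alpha:
        return PosthocResult(
            pairs=tuple(
                PairResult(pair, float("nan"), float("nan"), testable=False)
                for pair in all_pairs
            ),
            method=method,
            note=f"omnibus p={omnibus.p:.3g} >= {alpha}; no post-hoc testing",
        )

    if method == "wilcoxon-holm":
        return _posthoc_wilcoxon_holm(m, all_pairs)
    if method == "siegel-castellan":
        return _posthoc_siegel_castellan(m, all_pairs, alpha)
    raise ValueError(f"unknown post-hoc method {method!r}")


def _posthoc_wilcoxon_holm(m: CohortMatrix, all_pairs) -> PosthocResult:
    raw = []
    testable = []
    for a, b in all_pairs:
        paired = m.values[[a, b]].dropna()
        d = paired[a] - paired[b]
        if len(paired) < 2:
            raw.append(np.nan)
            testable.append(False)
        elif (d == 0).all():
            raw.append(1.0)
            testable.append(True)
        else:
            raw.append(float(stats.wilcoxon(paired[a], paired[b]).pvalue))
            testable.append(True)
    raw = np.asarray(raw)
    adjusted = np.full_like(raw, np.nan)
    ok = np.asarray(testable)
    if ok.any():
        adjusted[ok] = multipletests(raw[ok], method="holm")[1]
    return PosthocResult(
        pairs=tuple(
            PairResult(pair, float(r), float(adj), testable=t)
            for pair, r, adj, t in zip(all_pairs, raw, adjusted, ok)
        ),
        method="wilcoxon-holm",
    )


def _posthoc_siegel_castellan(m: CohortMatrix, all_pairs, alpha) -> PosthocResult:
    """Critical-difference comparisons of Friedman mean ranks (complete cases)."""
    data = m.complete_rows().to_numpy(dtype=float)
    labels = m.period_labels
    n, k = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    rbar = dict(zip(labels, ranks.mean(axis=0)))
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = len(all_pairs)
    pairs = []
    for a, b in all_pairs:
        z = abs(rbar[a] - rbar[b]) / se
        raw_p = 2.0 * float(stats.norm.sf(z))
        pairs.append(
            PairResult((a, b), raw_p, min(1.0, raw_p * n_pairs), testable=True)
        )
    return PosthocResult(pairs=tuple(pairs), method="siegel-castellan")


def mann_whitney(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U test (exact for small untied samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), 0, float(res.pvalue), "mann-whitney")
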