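"""Step-down many-to-one trend tests for dose-response endpoints.

Implements the statistical layer used for per-well screening metrics:

* a variance-heterogeneity gate (Bartlett's test) choosing between the
  parametric and the rank-based trend test;
* **Williams' test** — step-down comparison of each dose against the
  control assuming a monotone dose effect, using amalgamated (isotonic)
  dose-group means and a pooled within-group variance;
* **Shirley-Williams' test** — the rank analogue: at each step the
  control and the doses still in play are re-ranked jointly (midranks)
  and amalgamated mean ranks form the statistic;
* a two-group Student-t / Wilcoxon comparison.

Critical values for the amalgamated statistics are estimated once per
design by seeded Monte-Carlo simulation from the null (at least 1e5
replicates, cached per design), which reduces to the one-sided Student
t quantile at k = 1.  The trend tests are one-sided; the expected
direction must be declared per endpoint.  Defaults follow toxicology
screening practice: alpha = 0.025 for the trend tests, 0.05 for the
two-group comparison, significance stars at alpha, alpha/5, alpha/50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import isotonic_regression

WILLIAMS = "williams"
SHIRLEY_WILLIAMS = "shirley_williams"

_CRIT_CACHE: dict = {}


@dataclass
class DoseSeries:
    """Ordered dose-response observations (per-well metric values).

    ``doses`` are ordered by strictly increasing dose; ``direction`` is
    the alternative's monotone direction relative to control
    ("decreasing" for a toxicant suppressing the metric).
    """

    control: np.ndarray
    doses: list
    dose_labels: list = field(default_factory=list)
    direction: str = "decreasing"

    def __post_init__(self) -> None:
        self.control = np.asarray(self.control, dtype=float)
        self.doses = [np.asarray(d, dtype=float) for d in self.doses]
        if not self.dose_labels:
            self.dose_labels = [f"dose_{i + 1}" for i in range(len(self.doses))]
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")
        if len(self.doses) < 1:
            raise ValueError("at least one dose group is required")
        for arr in [self.control, *self.doses]:
            if arr.size < 2:
                raise ValueError("every group needs at least 2 observations")


@dataclass
class DoseDecision:
    label: str
    statistic: float
    critical_value: float
    significant: bool
    stars: int  # 0..3 at alpha, alpha/5, alpha/50


@dataclass
class GateResult:
    test: str
    heterogeneity_p: float
    reason: str = ""


@dataclass
class TrendResult:
    test: str
    alpha: float
    direction: str
    heterogeneity_p: float
    decisions: list  # ordered low -> high dose

    def significant_labels(self) -> list:
        return [d.label for d in self.decisions if d.significant]


@dataclass
class TwoGroupResult:
    test: str
    p_value: float
    significant: bool


def heterogeneity_gate(series: DoseSeries, alpha_het: float = 0.05) -> GateResult:
    """Choose the trend test by Bartlett's variance-homogeneity test.

    Heterogeneous variances (p < ``alpha_het``) select the rank-based
    Shirley-Williams test.  A group with zero variance (where Bartlett
    is undefined) also falls back to the rank test, unless every
    observation in every group is identical, which is treated as
    trivially homogeneous.
    """
    groups = [series.control, *series.doses]
    allvals = np.concatenate(groups)
    if np.all(allvals == allvals[0]):
        return GateResult(WILLIAMS, 1.0, "identical data, trivially homogeneous")
    if any(np.var(g) == 0 for g in groups):
        warnings.warn("zero-variance group; falling back to Shirley-Williams",
                      stacklevel=2)
        return GateResult(SHIRLEY_WILLIAMS, float("nan"), "zero-variance group")
    _, p = stats.bartlett(*groups)
    if p < alpha_het:
        return GateResult(SHIRLEY_WILLIAMS, float(p), "heterogeneous variances")
    return GateResult(WILLIAMS, float(p), "homogeneous variances")


def pava_isotonic_means(means, sizes, direction: str = "increasing") -> np.ndarray:
    """Weighted pool-adjacent-violators amalgamation of ordered group means.

    Returns means monotone in ``direction`` obtained by pooling adjacent
    violators; the pooled weighted mean is preserved.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    res = isotonic_regression(means, weights=sizes,
                              increasing=(direction == "increasing"))
    return np.asarray(res.x, dtype=float)


def _amalgamated_top(means: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Isotonic (increasing) fitted value of the last group.

    Equals the maximum over u of the weighted mean of groups u..k, the
    closed form of the PAVA fit at the top position.  Vectorized over
    leading axes of ``means`` (shape ``(..., k)``).
    """
    w = np.broadcast_to(sizes, means.shape)
    csum = np.cumsum((means * w)[..., ::-1], axis=-1)
    cw = np.cumsum(w[..., ::-1], axis=-1)
    return np.max(csum / cw, axis=-1)


def williams_critical_value(k: int, df: float, alpha: float = 0.025,
                            sizes=None, n_mc: int = 100_000,
                            seed: int = 12345) -> float:
    """One-sided critical value for the amalgamated Williams statistic.

    For ``k`` = 1 this is exactly the one-sided Student t quantile.  For
    ``k`` > 1 the null quantile of the step statistic is estimated by
    seeded Monte-Carlo (normal group means, chi-square pooled variance)
    and cached per design.  ``sizes`` gives the group sizes
    ``(n0, n1, ..., nk)``; equal sizes of 1 are assumed when omitted
    (the classical equal-n table layout).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return float(stats.t.ppf(1.0 - alpha, df)) if np.isfinite(df) \
            else float(stats.norm.ppf(1.0 - alpha))
    sizes = tuple(float(n) for n in (sizes if sizes is not None else [1.0] * (k + 1)))
    key = ("williams", k, float(df), float(alpha), sizes, int(n_mc), int(seed))
    if key in _CRIT_CACHE:
        return _CRIT_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence([seed, k, int(1e6 * alpha)]))
    n = np.asarray(sizes, dtype=float)
    means = rng.standard_normal((n_mc, k + 1)) / np.sqrt(n)
    if np.isfinite(df):
        s = np.sqrt(rng.chisquare(df, size=n_mc) / df)
    else:
        s = np.ones(n_mc)
    top = _amalgamated_top(means[:, 1:], n[1:])
    se = s * np.sqrt(1.0 / n[k] + 1.0 / n[0])
    stat = (top - means[:, 0]) / se
    crit = float(np.quantile(stat, 1.0 - alpha))
    _CRIT_CACHE[key] = crit
    return crit


def _shirley_critical_value(k: int, sizes, alpha: float = 0.025,
                            n_mc: int = 100_000, seed: int = 12345) -> float:
    """Null quantile of the top-step rank statistic for a given design.

    Simulated from continuous exchangeable data, so the estimate is
    distribution-free; cached per design.
    """
    sizes = tuple(int(n) for n in sizes)
    key = ("shirley", k, sizes, float(alpha), int(n_mc), int(seed))
    if key in _CRIT_CACHE:
        return _CRIT_CACHE[key]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7 + k, int(1e6 * alpha)]))
    n = np.asarray(sizes, dtype=float)
    N = int(n.sum())
    data = rng.standard_normal((n_mc, N))
    ranks = stats.rankdata(data, axis=1)
    bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    group_means = np.stack(
        [ranks[:, bounds[i]:bounds[i + 1]].mean(axis=1) for i in range(k + 1)],
        axis=1,
    )
    v = N * (N + 1) / 12.0
    top = _amalgamated_top(group_means[:, 1:], n[1:])
    stat = (top - group_means[:, 0]) / np.sqrt(v * (1.0 / n[k] + 1.0 / n[0]))
    crit = float(np.quantile(stat, 1.0 - alpha))
    _CRIT_CACHE[key] = crit
    return crit


def _oriented(series: DoseSeries) -> tuple[np.ndarray, list]:
    """Flip the sign for decreasing alternatives so tests are one-sided up."""
    sign = -1.0 if series.direction == "decreasing" else 1.0
    return sign * series.control, [sign * d for d in series.doses]


_STAR_DIVISORS = (1.0, 5.0, 50.0)  # alpha, alpha/5, alpha/50


def williams_test(series: DoseSeries, alpha: float = 0.025,
                  n_mc: int = 100_000, seed: int = 12345,
                  heterogeneity_p: float = float("nan")) -> TrendResult:
    """Williams' step-down trend test against the control.

    At each step (highest remaining dose k) the statistic is the
    amalgamated mean of doses 1..k at the top position minus the control
    mean, scaled by the pooled within-group standard error, compared to
    the one-sided Monte-Carlo critical value for a k-dose design.  The
    step-down stops at the first non-significant dose, so lower doses
    can never be flagged after a non-significant higher dose.
    """
    control, doses = _oriented(series)
    groups = [control, *doses]
    sizes = np.array([g.size for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    df = float(sizes.sum() - len(groups))
    ss = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    s2 = ss / df if df > 0 else 0.0
    K = len(doses)
    decisions: list[DoseDecision] = [None] * K
    active = True
    for j in range(K, 0, -1):
        top = float(_amalgamated_top(means[1:j + 1][None, :], sizes[1:j + 1])[0])
        se = np.sqrt(s2 * (1.0 / sizes[j] + 1.0 / sizes[0]))
        if se == 0:
            stat = 0.0 if top <= means[0] else float("inf")
        else:
            stat = (top - means[0]) / se
        crit = williams_critical_value(j, df, alpha, sizes[: j + 1], n_mc, seed)
        sig = active and stat > crit
        stars = 0
        if sig:
            for div in _STAR_DIVISORS:
                c = williams_critical_value(j, df, alpha / div,
                                            sizes[: j + 1], n_mc, seed)
                if stat > c:
                    stars += 1
        decisions[j - 1] = DoseDecision(series.dose_labels[j - 1], float(stat),
                                        float(crit), bool(sig), stars)
        if not sig:
            active = False
    return TrendResult(WILLIAMS, alpha, series.direction,
                       heterogeneity_p, decisions)


def shirley_williams_test(series: DoseSeries, alpha: float = 0.025,
                          n_mc: int = 100_000, seed: int = 12345,
                          heterogeneity_p: float = float("nan")) -> TrendResult:
    """Shirley-Williams' rank-based step-down trend test.

    At each step the control and the doses still in play are re-ranked
    jointly (midranks for ties); amalgamated mean ranks form the
    statistic against the control mean rank with the rank-variance
    scaling (tie-corrected), compared to design-specific Monte-Carlo
    critical values.  Invariant under strictly increasing transforms of
    the observations.
    """
    control, doses = _oriented(series)
    K = len(doses)
    n0 = control.size
    decisions: list[DoseDecision] = [None] * K
    active = True
    for j in range(K, 0, -1):
        groups = [control, *doses[:j]]
        sizes = np.array([g.size for g in groups], dtype=float)
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        N = pooled.size
        bounds = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        gmeans = np.array([ranks[bounds[i]:bounds[i + 1]].mean()
                           for i in range(j + 1)])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3 - counts).sum()) / (N ** 3 - N)) \
            if N > 1 else 0.0
        v = (N * (N + 1) / 12.0) * (1.0 - tie_term)
        top = float(_amalgamated_top(gmeans[1:][None, :], sizes[1:])[0])
        se = np.sqrt(v * (1.0 / sizes[j] + 1.0 / n0))
        if se == 0:
            stat = 0.0 if top <= gmeans[0] else float("inf")
        else:
            stat = (top - gmeans[0]) / se
        crit = _shirley_critical_value(j, sizes.astype(int), alpha, n_mc, seed)
        sig = active and stat > crit
        stars = 0
        if sig:
            for div in _STAR_DIVISORS:
                c = _shirley_critical_value(j, sizes.astype(int), alpha / div,
                                            n_mc, seed)
                if stat > c:
                    stars += 1
        decisions[j - 1] = DoseDecision(series.dose_labels[j - 1], float(stat),
                                        float(crit), bool(sig), stars)
        if not sig:
            active = False
    return TrendResult(SHIRLEY_WILLIAMS, alpha, series.direction,
                       heterogeneity_p, decisions)


def run_trend(series: DoseSeries, alpha: float = 0.025,
              alpha_het: float = 0.05, n_mc: int = 100_000,
              seed: int = 12345) -> TrendResult:
    """Gate on variance heterogeneity, then run the selected trend test."""
    gate = heterogeneity_gate(series, alpha_het)
    if gate.test == WILLIAMS:
        return williams_test(series, alpha, n_mc, seed, gate.heterogeneity_p)
    return shirley_williams_test(series, alpha, n_mc, seed, gate.heterogeneity_p)


def two_group_test(control, treated, alpha: float = 0.05,
                   method: str = "auto") -> TwoGroupResult:
    """Two-sided two-group comparison (Student t or Wilcoxon rank sum).

    With ``method="auto"`` Student's t is used when an F-test accepts
    variance homogeneity at 0.05, otherwise the Wilcoxon rank-sum
    (Mann-Whitney) test, exact for small tie-free samples; either test
    can also be requested explicitly.  The difference is significant
    when p < ``alpha``.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TwoGroupResult("wilcoxon" if method == "wilcoxon" else "student_t",
                              1.0, False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("degenerate input: both groups constant but different")
    if method == "auto":
        if va > 0 and vb > 0:
            f = va / vb
            p_f = 2.0 * min(stats.f.cdf(f, a.size - 1, b.size - 1),
                            stats.f.sf(f, a.size - 1, b.size - 1))
        else:
            p_f = 0.0  # one constant group: variances clearly unequal
        method = "wilcoxon" if p_f < 0.05 else "student_t"
    if method == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return TwoGroupResult("wilcoxon", float(res.pvalue),
                              bool(res.pvalue < alpha))
    if method != "student_t":
        raise ValueError(f"unknown method {method!r}")
    res = stats.ttest_ind(a, b, equal_var=True)
    return TwoGroupResult("student_t", float(res.pvalue),
                          bool(res.pvalue < alpha))
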