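"""Trend statistics: gate, PAVA, Williams/Shirley-Williams, two-group test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from sarcoscreen.trend import (
    SHIRLEY_WILLIAMS,
    WILLIAMS,
    DoseSeries,
    heterogeneity_gate,
    pava_isotonic_means,
    run_trend,
    shirley_williams_test,
    two_group_test,
    williams_critical_value,
    williams_test,
)


def _pava_bruteforce(means, sizes):
    """Oracle: smallest weighted SSE over all monotone block partitions."""
    means = np.asarray(means, float)
    sizes = np.asarray(sizes, float)
    k = len(means)
    best, best_sse = None, np.inf
    # every composition of k into consecutive blocks
    for cuts in itertools.product([0, 1], repeat=k - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, k))
        fit = np.empty(k)
        for a, b in blocks:
            fit[a:b] = np.average(means[a:b], weights=sizes[a:b])
        if np.all(np.diff(fit) >= -1e-12):
            sse = float(np.sum(sizes * (means - fit) ** 2))
            if sse < best_sse - 1e-12:
                best, best_sse = fit, sse
    return best


class TestPava:
    def test_monotone_input_unchanged(self):
        out = pava_isotonic_means([1.0, 2.0, 3.0], [2, 2, 2], "increasing")
        assert np.allclose(out, [1.0, 2.0, 3.0])

    def test_violating_triplet_fully_pooled(self):
        out = pava_isotonic_means([3.0, 1.0, 2.0], [1, 1, 1], "increasing")
        assert np.allclose(out, [2.0, 2.0, 2.0])

    def test_decreasing_direction(self):
        out = pava_isotonic_means([1.0, 3.0, 2.0], [1, 1, 1], "decreasing")
        assert np.all(np.diff(out) <= 1e-12)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=6),
           st.lists(st.integers(1, 9), min_size=6, max_size=6))
    def test_matches_bruteforce_and_conserves_mean(self, means, sizes):
        sizes = sizes[: len(means)]
        out = pava_isotonic_means(means, sizes, "increasing")
        oracle = _pava_bruteforce(means, sizes)
        assert np.allclose(out, oracle, atol=1e-8)
        assert np.average(out, weights=sizes) == pytest.approx(
            np.average(means, weights=sizes))
        assert np.all(np.diff(out) >= -1e-9)


class TestGate:
    def test_identical_data_selects_williams(self):
        s = DoseSeries([1.0, 1.0], [[1.0, 1.0], [1.0, 1.0]])
        gate = heterogeneity_gate(s)
        assert gate.test == WILLIAMS
        assert gate.heterogeneity_p == 1.0

    def test_zero_variance_group_falls_back(self):
        s = DoseSeries([1.0, 2.0, 3.0], [[2.0, 2.0, 2.0]])
        with pytest.warns(UserWarning):
            gate = heterogeneity_gate(s)
        assert gate.test == SHIRLEY_WILLIAMS

    def test_gross_heterogeneity_detected(self):
        rng = np.random.default_rng(0)
        s = DoseSeries(rng.normal(0, 1, 6),
                       [rng.normal(0, 1, 6), rng.normal(0, 1, 6),
                        rng.normal(0, 10, 6)])
        assert heterogeneity_gate(s).test == SHIRLEY_WILLIAMS

    def test_gate_size_matches_bartlett_alpha(self):
        # under homogeneous normals the rank test is chosen ~5% of the time
        rng = np.random.default_rng(7)
        chosen = 0
        n = 10_000
        for _ in range(n):
            g = rng.normal(0, 1, (4, 6))
            s = DoseSeries(g[0], list(g[1:]))
            chosen += heterogeneity_gate(s).test == SHIRLEY_WILLIAMS
        assert abs(chosen / n - 0.05) <= 0.01


class TestCriticalValues:
    def test_k1_equals_student_t(self):
        assert williams_critical_value(1, 10, 0.025) == pytest.approx(
            spstats.t.ppf(0.975, 10), abs=1e-9)

    def test_nondecreasing_in_k(self):
        sizes = [6, 6, 6, 6]
        vals = [williams_critical_value(k, 20, 0.025, sizes[: k + 1])
                for k in (1, 2, 3)]
        assert vals[0] <= vals[1] + 1e-6 and vals[1] <= vals[2] + 1e-6

    def test_deterministic_given_seed(self):
        a = williams_critical_value(3, 20, 0.025, [6, 6, 6, 6], seed=99)
        b = williams_critical_value(3, 20, 0.025, [6, 6, 6, 6], seed=99)
        assert a == b


def _null_series(rng, k=3, n=6, dist="normal"):
    if dist == "normal":
        g = rng.normal(0, 1, (k + 1, n))
    else:
        g = rng.standard_t(2, (k + 1, n))
    return DoseSeries(g[0], list(g[1:]))


class TestWilliams:
    def test_constant_data_nothing_significant(self):
        s = DoseSeries([2.0, 2.0, 2.0], [[2.0] * 3, [2.0] * 3])
        res = williams_test(s)
        assert not any(d.significant for d in res.decisions)

    def test_reduces_to_t_for_single_dose(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(-2, 1, 6)
        res = williams_test(DoseSeries(a, [b], direction="decreasing"))
        t_stat, _ = spstats.ttest_ind(a, b, equal_var=True)
        assert res.decisions[0].statistic == pytest.approx(abs(t_stat) * np.sign(t_stat))

    def test_strong_effect_detected_with_coherence(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(200):
            s = DoseSeries(rng.normal(0, 1, 6),
                           [rng.normal(-0.5, 1, 6), rng.normal(-2, 1, 6),
                            rng.normal(-5, 1, 6)])
            res = williams_test(s)
            sig = [d.significant for d in res.decisions]
            # step-down coherence: nonsignificant dose blocks all lower doses
            for i in range(len(sig) - 1):
                if not sig[i + 1]:
                    assert not sig[i]
            hits += sig[-1]
        assert hits >= 198

    def test_null_size_small_sample(self):
        rng = np.random.default_rng(5)
        rej = sum(
            any(d.significant for d in williams_test(_null_series(rng)).decisions)
            for _ in range(3000)
        )
        assert 0.01 <= rej / 3000 <= 0.045


class TestShirleyWilliams:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        g = rng.normal(0, 1, (4, 6))
        s1 = DoseSeries(g[0], list(g[1:]))
        transformed = np.exp(g) + 5.0
        s2 = DoseSeries(transformed[0], list(transformed[1:]))
        r1 = shirley_williams_test(s1)
        r2 = shirley_williams_test(s2)
        assert [d.significant for d in r1.decisions] \
            == [d.significant for d in r2.decisions]

    def test_constant_data_nothing_significant(self):
        s = DoseSeries([2.0, 2.0, 2.0], [[2.0] * 3, [2.0] * 3])
        res = shirley_williams_test(s)
        assert not any(d.significant for d in res.decisions)

    def test_null_size_heavy_tails(self):
        rng = np.random.default_rng(8)
        rej = sum(
            any(d.significant
                for d in shirley_williams_test(_null_series(rng, dist="t")).decisions)
            for _ in range(3000)
        )
        assert 0.008 <= rej / 3000 <= 0.042

    def test_power_nondecreasing_in_effect(self):
        rng = np.random.default_rng(9)
        powers = []
        for shift in (0.0, 2.0, 5.0):
            hits = 0
            for _ in range(150):
                s = DoseSeries(
                    rng.normal(0, 1, 6),
                    [rng.normal(-shift / 4, 1, 6), rng.normal(-shift / 2, 1, 6),
                     rng.normal(-shift, 1, 6)])
                hits += shirley_williams_test(s).decisions[-1].significant
            powers.append(hits / 150)
        assert powers[0] <= powers[1] <= powers[2]


class TestTwoGroup:
    def test_identical_groups_p_one(self):
        res = two_group_test([1, 2, 3, 4], [1, 2, 3, 4], method="wilcoxon")
        assert res.p_value == pytest.approx(1.0, abs=0.01)
        assert not res.significant

    def test_exact_rank_sum_p(self):
        res = two_group_test([1, 2, 3, 4, 5, 6], [11, 12, 13, 14, 15, 16],
                             method="wilcoxon")
        assert res.p_value == pytest.approx(2 / 924, rel=1e-9)
        assert res.significant

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 6), rng.normal(1, 2, 6)
        assert two_group_test(a, b).p_value == pytest.approx(
            two_group_test(b, a).p_value)

    def test_degenerate_constant_groups_raise(self):
        with pytest.raises(ValueError):
            two_group_test([1.0, 1.0], [2.0, 2.0])


class TestRunTrend:
    def test_gate_dispatch(self):
        rng = np.random.default_rng(11)
        s = DoseSeries(rng.normal(0, 1, 6),
                       [rng.normal(0, 1, 6), rng.normal(0, 12, 6)])
        res = run_trend(s)
        assert res.test == SHIRLEY_WILLIAMS

    def test_increasing_direction(self):
        rng = np.random.default_rng(12)
        s = DoseSeries(rng.normal(0, 1, 6),
                       [rng.normal(2, 1, 6), rng.normal(5, 1, 6)],
                       direction="increasing")
        res = run_trend(s)
        assert res.decisions[-1].significant
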