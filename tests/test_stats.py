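import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metaboscore.stats import (
    ConvergenceError,
    InsufficientDataError,
    cox_ph,
    filter_survival,
    km_estimate,
    logrank,
    mann_whitney,
    median_split,
    spearman,
)


# ---------------------------------------------------------------------------
# Mann-Whitney

def _mwu_exact_oracle(x, y):
    """Two-sided exact p by brute-force enumeration of all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n = len(x), len(x) + len(y)
    mu = len(x) * len(y) / 2.0

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
            1.0 for a in xs for b in ys if a == b
        )

    u_obs = u_of(tuple(range(n1)))
    total = hits = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_spec_example_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(1 / 3)

    def test_identical_multisets(self):
        x = [1.0, 2.0, 5.0]
        res = mann_whitney(x, list(x))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.pvalue == pytest.approx(1.0)

    def test_all_values_identical_zero_variance(self):
        res = mann_whitney([3, 3, 3], [3, 3])
        assert res.pvalue == 1.0
        assert res.flags["zero_variance"]

    @given(
        x=st.lists(st.integers(0, 50), min_size=1, max_size=8),
        y=st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    def test_u_complement_identity(self, x, y):
        uxy = mann_whitney(x, y).statistic
        uyx = mann_whitney(y, x).statistic
        assert uxy + uyx == pytest.approx(len(x) * len(y))

    def test_exact_matches_bruteforce_oracle(self, rng):
        for _ in range(15):
            n1, n2 = rng.integers(1, 6, size=2)
            vals = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = vals[:n1], vals[n1:]
            assert mann_whitney(x, y).pvalue == pytest.approx(_mwu_exact_oracle(x, y))

    def test_asymptotic_matches_scipy(self, rng):
        x = rng.integers(0, 10, size=30).astype(float)
        y = rng.integers(2, 12, size=25).astype(float)
        res = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic")
        assert not res.flags["exact"]
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-10)

    def test_exact_mode_with_ties_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 1], [2], mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            mann_whitney([], [1.0])


# ---------------------------------------------------------------------------
# Spearman

class TestSpearman:
    def test_monotone_increasing(self):
        x = [1, 2, 5, 9, 12]
        y = [0.1, 3, 4, 100, 200]
        assert spearman(x, y).effect == pytest.approx(1.0)

    def test_reversed_ranks(self):
        x = [1, 2, 3, 4]
        assert spearman(x, x[::-1]).effect == pytest.approx(-1.0)

    def test_ties_match_pearson_of_ranks_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0]
        y = [4.0, 4.0, 1.0, 2.0, 9.0, 9.0, 3.0, 7.0]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y).effect == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.effect == pytest.approx(ref.statistic, abs=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_flagged(self):
        res = spearman([1, 1, 1], [1, 2, 3])
        assert math.isnan(res.effect)
        assert res.flags["constant_input"]

    def test_too_small(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# survival filtering / median split

class TestFilterSurvival:
    def test_early_death_removed(self):
        df = pd.DataFrame({"time": [0.5], "event": [True]})
        assert len(filter_survival(df)) == 0

    def test_early_censoring_retained(self):
        df = pd.DataFrame({"time": [0.5], "event": [False]})
        out = filter_survival(df)
        assert len(out) == 1
        assert out.attrs["n_excluded_early_deaths"] == 0

    def test_empty_input(self):
        df = pd.DataFrame({"time": [], "event": []})
        assert len(filter_survival(df)) == 0

    def test_boundary_inclusive(self):
        df = pd.DataFrame({"time": [1.0, 1.01], "event": [True, True]})
        out = filter_survival(df)
        assert out.time.tolist() == [1.01]


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1, 2, 3, 4])
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = median_split([1, 2, 2, 3])
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            median_split([5, 5, 5])


# ---------------------------------------------------------------------------
# Kaplan-Meier

class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        times = [2.0, 5.0, 7.0, 11.0]
        km = km_estimate(times, [True] * 4)
        # S after the k-th death = (4 - k) / 4
        surv = km[km.n_events > 0].survival.tolist()
        assert surv == pytest.approx([3 / 4, 2 / 4, 1 / 4, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False] * 3)
        assert (km.survival == 1.0).all()

    def test_hand_computed_product_limit(self):
        # censored at 3, death at 5: risk set of 1 at t=5, so S(5) = 0
        km = km_estimate([3.0, 5.0], [False, True])
        assert km[km.time == 5.0].survival.iloc[0] == pytest.approx(0.0)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 80)
        e = rng.random(80) < 0.6
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert row.survival == pytest.approx(
                float(kmf.survival_function_at_times(row.time).iloc[0]), abs=1e-12
            )

    def test_monotone_right_continuous_s0(self, rng):
        t = rng.exponential(10, 50)
        e = rng.random(50) < 0.7
        km = km_estimate(t, e)
        assert km.survival.iloc[0] == 1.0 and km.time.iloc[0] == 0.0
        assert (np.diff(km.survival) <= 1e-12).all()
        assert ((km.ci_low <= km.survival + 1e-12) & (km.survival <= km.ci_high + 1e-12)).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


# ---------------------------------------------------------------------------
# logrank

class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [True] * 6
        g = ["a"] * 3 + ["b"] * 3
        res = logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.8
        g = rng.choice(["a", "b"], 40)
        res1 = logrank(t, e, g)
        res2 = logrank(t, e, np.where(g == "a", "b", "a"))
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_matches_lifelines_multigroup(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        t = rng.exponential(10, 90)
        e = rng.random(90) < 0.7
        g = rng.choice(["a", "b", "c"], 90)
        res = logrank(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.pvalue == pytest.approx(ref.p_value, rel=1e-9)
        assert res.df == 2

    def test_two_group_equals_squared_standardized_oe(self, rng):
        # for k = 2 the chi-square is (O - E)^2 / Var for either group
        from lifelines.statistics import logrank_test

        t = rng.exponential(5, 60)
        e = rng.random(60) < 0.9
        g = rng.choice(["x", "y"], 60)
        res = logrank(t, e, g)
        ref = logrank_test(t[g == "x"], t[g == "y"], e[g == "x"], e[g == "y"])
        assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_power_under_hr2(self, rng):
        # HR = 2, n = 500/arm: near-certain rejection
        rejections = 0
        for _ in range(40):
            t1 = rng.exponential(10, 500)
            t2 = rng.exponential(5, 500)
            t = np.concatenate([t1, t2])
            e = np.ones(1000, dtype=bool)
            g = np.repeat(["a", "b"], 500)
            if logrank(t, e, g).pvalue < 0.05:
                rejections += 1
        assert rejections >= 38  # >= 95%

    def test_needs_events_and_groups(self):
        with pytest.raises(InsufficientDataError):
            logrank([1, 2], [False, False], ["a", "b"])
        with pytest.raises(InsufficientDataError):
            logrank([1, 2], [True, True], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox

def _breslow_loglik_oracle(beta, times, events, x):
    """Breslow partial log-likelihood written out directly from the formula."""
    ll = 0.0
    for t in np.unique(np.asarray(times)[np.asarray(events, dtype=bool)]):
        deaths = [i for i in range(len(times)) if events[i] and times[i] == t]
        risk = [i for i in range(len(times)) if times[i] >= t]
        ll += sum(beta * x[i] for i in deaths)
        ll -= len(deaths) * math.log(sum(math.exp(beta * x[i]) for i in risk))
    return ll


def _golden_section_max(f, lo=-8.0, hi=8.0, tol=1e-10):
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    while abs(b - a) > tol:
        if f(c) > f(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    return (a + b) / 2


class TestCox:
    def test_tiny_dataset_matches_bruteforce_likelihood(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True, True, False, True, True, True]
        x = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        df = pd.DataFrame({"time": times, "event": events, "x": x})
        fit = cox_ph(df, ["x"])
        # centering does not change the coefficient
        xc = np.asarray(x) - np.mean(x)
        beta_star = _golden_section_max(
            lambda b: _breslow_loglik_oracle(b, times, events, xc)
        )
        assert fit.coef.iloc[0] == pytest.approx(beta_star, abs=1e-6)

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.choice([0.0, 1.0], n)
        t = rng.exponential(1 / (0.05 * np.exp(0.4 * x1 + 0.7 * x2)))
        e = rng.random(n) < 0.8
        df = pd.DataFrame({"time": t, "event": e, "x1": x1, "x2": x2})
        fit = cox_ph(df, ["x1", "x2"])
        ref = CoxPHFitter().fit(df, "time", "event")  # Efron = Breslow with no ties
        np.testing.assert_allclose(fit.coef.values, ref.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se.values, ref.standard_errors_.values, atol=1e-5)

    def test_hr2_parameter_recovery(self, rng):
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.02 * 2.0 ** x))
        c = rng.uniform(0, 120, n)
        time = np.minimum(t, c)
        event = t <= c
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = cox_ph(df, ["x"])
        assert 1.8 <= fit.hr.iloc[0] <= 2.2

    def test_null_covariate_ci_coverage(self, rng):
        covered = 0
        reps = 150
        for _ in range(reps):
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(10, n)
            e = rng.random(n) < 0.8
            df = pd.DataFrame({"time": t, "event": e, "x": x})
            fit = cox_ph(df, ["x"])
            if fit.hr_ci_low.iloc[0] <= 1.0 <= fit.hr_ci_high.iloc[0]:
                covered += 1
        assert 0.90 <= covered / reps <= 0.99

    def test_categorical_encoding_reference_level(self):
        df = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 6, 7, 8.0],
            "event": [True] * 8,
            "stage": ["I", "II", "I", "II", "I", "II", "I", "II"],
        })
        fit = cox_ph(df, ["stage"])
        assert fit.covariate.tolist() == ["stage[II vs I]"]

    def test_separation_flagged(self):
        # covariate perfectly orders survival: monotone likelihood
        df = pd.DataFrame({
            "time": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0],
            "event": [True] * 6,
            "x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0],
        })
        with pytest.raises(ConvergenceError):
            cox_ph(df, ["x"])

    def test_efron_not_silently_accepted(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [True, True], "x": [0.0, 1.0]})
        with pytest.raises(NotImplementedError):
            cox_ph(df, ["x"], ties="efron")

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False], "x": [0.0, 1.0]})
        with pytest.raises(InsufficientDataError):
            cox_ph(df, ["x"])
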