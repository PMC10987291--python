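"""Survival machinery against hand calculations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmaquant import (
    CohortConfig,
    CutpointParams,
    bootstrap_median_ci,
    concordance_index,
    cutpoint_search,
    generate_cohort,
    km_estimate,
    logrank_test,
    subgroup_km,
)


def brute_force_logrank(times, events, groups):
    """Direct summation of hypergeometric terms at every distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    g = np.asarray(groups)
    lab = np.unique(g)[0]
    o_minus_e = 0.0
    var = 0.0
    for u in sorted(set(times[events])):
        at = times >= u
        n, n1 = at.sum(), (at & (g == lab)).sum()
        d = (events & (times == u)).sum()
        d1 = (events & (times == u) & (g == lab)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2, float(stats.chi2.sf(chi2, 1)) if var > 0 else 1.0


def brute_force_concordance(manual, scores):
    conc = ties = comparable = 0
    n = len(manual)
    for i in range(n):
        for j in range(i + 1, n):
            if manual[i] == manual[j]:
                continue
            comparable += 1
            ds = scores[i] - scores[j]
            dm = manual[i] - manual[j]
            if ds == 0:
                ties += 1
            elif (ds > 0) == (dm > 0):
                conc += 1
    return (conc + 0.5 * ties) / comparable


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([2.0, 5.0, 7.0], [0, 0, 0])
        assert np.all(km.survival == 1.0)

    def test_hand_product_limit_calculation(self):
        """Event at 1 of 3, censor at 2, event at 3 of 1: S = 2/3 then 0."""
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.survival_at(0.5) == 1.0

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10.0, 200)
        km = km_estimate(t, np.ones(200))
        emp = np.array([(t > u).mean() for u in km.times])
        assert np.allclose(km.survival, emp, atol=1e-12)

    def test_agreement_with_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(5, 80))
            t = rng.integers(1, 20, n).astype(float)
            e = rng.integers(0, 2, n)
            km = km_estimate(t, e)
            ref = KaplanMeierFitter().fit(t, e).survival_function_at_times(km.times)
            assert np.abs(km.survival - ref.to_numpy()).max() < 1e-12

    def test_survival_non_increasing(self):
        rng = np.random.default_rng(2)
        km = km_estimate(rng.integers(1, 30, 100), rng.integers(0, 2, 100))
        assert np.all(np.diff(km.survival) <= 1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_duplicated_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 0, 1, 1, 1, 0, 1, 1]
        g = [0] * 4 + [1] * 4
        stat, p = logrank_test(t, e, g)
        assert stat == 0.0 and p == 1.0

    def test_four_patient_worked_example_matches_enumeration(self):
        t = [1, 3, 2, 4]
        e = [1, 1, 1, 1]
        g = ["A", "A", "B", "B"]
        stat, p = logrank_test(t, e, g)
        bstat, bp = brute_force_logrank(t, e, g)
        assert stat == pytest.approx(bstat, abs=1e-12)
        assert p == pytest.approx(bp, abs=1e-12)

    def test_matches_brute_force_on_random_cohorts_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 60))
            t = rng.integers(1, 10, n).astype(float)
            e = rng.integers(0, 2, n)
            g = rng.integers(0, 2, n)
            if len(set(g)) < 2 or e.sum() == 0:
                continue
            assert logrank_test(t, e, g) == pytest.approx(
                brute_force_logrank(t, e, g), abs=1e-12
            )

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(5, 50)
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        assert logrank_test(t, e, g) == pytest.approx(logrank_test(t, e, 1 - g))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCutpointSearch:
    def test_exactly_50_equidistant_thresholds(self):
        df = generate_cohort(CohortConfig(seed=5))
        res = cutpoint_search(df)
        assert res.thresholds.size == 50
        steps = np.diff(res.thresholds)
        assert np.allclose(steps, steps[0])
        assert np.all(np.diff(res.thresholds) > 0)
        lo, hi = df["score"].min(), df["score"].max()
        assert lo < res.thresholds[0] and res.thresholds[-1] < hi

    def test_admissible_thresholds_respect_group_floor(self):
        df = generate_cohort(CohortConfig(seed=6))
        res = cutpoint_search(df)
        n = len(df)
        smaller = np.minimum(res.n_high, res.n_low)
        assert np.all(smaller[res.admissible] >= 0.15 * n)
        assert res.n_tests == int(res.admissible.sum())
        assert res.admissible[res.best_index]

    def test_constant_scores_yield_no_admissible_cutpoint(self):
        df = pd.DataFrame(
            {"score": np.ones(40), "time": np.arange(1, 41), "event": [1] * 40}
        )
        res = cutpoint_search(df)
        assert res.no_admissible and res.best_threshold is None

    def test_too_few_patients_rejected(self):
        df = pd.DataFrame({"score": [1.0, 2.0], "time": [1, 2], "event": [1, 1]})
        with pytest.raises(ValueError, match="at least"):
            cutpoint_search(df)

    def test_minimum_p_over_grid_is_anticonservative_under_null(self):
        """Best-p < 0.05 far exceeds 5% under the null: raw p needs context."""
        hits = 0
        reps = 100
        for seed in range(reps):
            df = generate_cohort(CohortConfig(n_patients=120, hazard_ratio=1.0, seed=seed))
            res = cutpoint_search(df)
            hits += res.best_p < 0.05
        assert hits / reps > 0.12

    def test_determinism(self):
        df = generate_cohort(CohortConfig(seed=7))
        a, b = cutpoint_search(df), cutpoint_search(df)
        assert a.best_index == b.best_index
        assert np.array_equal(a.p_value, b.p_value, equal_nan=True)


class TestSubgroupKM:
    def test_full_cohort_consistent_with_search(self):
        df = generate_cohort(CohortConfig(seed=8))
        res = cutpoint_search(df)
        sub = subgroup_km(df, res.best_threshold)
        assert sub.p_value == pytest.approx(res.best_p, abs=1e-12)

    def test_one_sided_subgroup_not_evaluable(self):
        df = generate_cohort(CohortConfig(seed=9))
        low = df["score"].quantile(0.1)
        df.loc[df["score"] <= low, "subgroup"] = "tiny"
        r = subgroup_km(df, threshold=low, subgroup="tiny")
        assert not r.evaluable and r.p_value is None

    def test_nonfinite_scores_excluded_from_split(self):
        """A NaN score (undefined ratio) must not be lumped into a group."""
        df = generate_cohort(CohortConfig(n_patients=60, seed=15))
        df.loc[df.index[:5], "score"] = np.nan
        res = cutpoint_search(df)
        sub = subgroup_km(df, res.best_threshold)
        assert sub.n_high + sub.n_low == 55
        assert sub.p_value == pytest.approx(res.best_p, abs=1e-12)

    def test_null_subgroup_p_values_uniform(self):
        """Re-testing an independent null subgroup gives uniform p (KS check)."""
        pvals = []
        for seed in range(500):
            main = generate_cohort(
                CohortConfig(n_patients=300, hazard_ratio=3.0, seed=2 * seed)
            )
            null = generate_cohort(
                CohortConfig(n_patients=100, hazard_ratio=1.0,
                             subgroup_labels=("null",), seed=2 * seed + 1)
            )
            res = cutpoint_search(main)
            r = subgroup_km(pd.concat([main, null]), res.best_threshold, "null")
            if r.evaluable:
                pvals.append(r.p_value)
        assert len(pvals) > 450
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestConcordance:
    def test_perfect_and_reversed_orderings(self):
        manual = ["negative", "inconclusive", "scattered positive", "positive"]
        scores = np.array([0.1, 0.2, 0.5, 2.0])
        assert concordance_index(manual, scores) == 1.0
        assert concordance_index(manual, -scores) == 0.0

    def test_six_patient_mixed_example_matches_brute_force(self):
        manual = np.array([0, 0, 1, 2, 2, 3])
        scores = np.array([0.3, 0.1, 0.1, 0.8, 0.4, 0.6])
        assert concordance_index(manual, scores) == pytest.approx(
            brute_force_concordance(manual, scores), abs=1e-15
        )

    def test_random_fixtures_match_brute_force(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            manual = rng.integers(0, 4, 50)
            scores = np.round(rng.uniform(0, 1, 50), 2)  # induce ties
            assert concordance_index(manual, scores) == pytest.approx(
                brute_force_concordance(manual, scores), abs=1e-15
            )

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        manual = rng.integers(0, 4, 30)
        if len(set(manual)) < 2:
            manual[0], manual[1] = 0, 3
        scores = rng.uniform(0, 5, 30)
        c1 = concordance_index(manual, scores)
        c2 = concordance_index(manual, np.log1p(scores) * 7 + 3)
        assert c1 == pytest.approx(c2, abs=1e-15)

    def test_all_identical_manual_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1, 1, 1], [0.1, 0.2, 0.3])

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="weird"):
            concordance_index(["negative", "weird"], [0.1, 0.2])


def test_km_plot_written_to_file(tmp_path):
    from tmaquant.survival import plot_km

    df = generate_cohort(CohortConfig(n_patients=80, seed=13))
    high = df["score"] > df["score"].median()
    curves = {
        "high": km_estimate(df.loc[high, "time"], df.loc[high, "event"]),
        "low": km_estimate(df.loc[~high, "time"], df.loc[~high, "event"]),
    }
    out = tmp_path / "km.png"
    fig = plot_km(curves, title="demo", path=out)
    assert out.stat().st_size > 0
    assert len(fig.axes) == 1


class TestBootstrapMedianCI:
    def test_constant_values_give_degenerate_interval(self):
        out = bootstrap_median_ci({"a": [3.0] * 20}, n_boot=200, seed=0)
        ci = out["a"]
        assert ci.median == ci.lower == ci.upper == 3.0

    def test_same_seed_reproduces_interval(self):
        vals = {"a": np.random.default_rng(0).normal(size=30)}
        a = bootstrap_median_ci(vals, n_boot=500, seed=42)
        b = bootstrap_median_ci(vals, n_boot=500, seed=42)
        assert a == b

    def test_empty_category_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = bootstrap_median_ci({"a": [1.0, 2.0], "b": []}, n_boot=100, seed=1)
        assert "b" not in out and "a" in out
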