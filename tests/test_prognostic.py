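import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank

from ecckit.prognostic import (
    km_estimate,
    logrank_statistic,
    logrank_test,
    optimal_cutpoint,
    prognostic_classifier,
    survival_screen,
    univariate_cox,
)


def exhaustive_scan_oracle(values, times, events, bounds=(0.10, 0.90), min_group=3):
    """Independent cutoff scan using the lifelines log-rank test."""
    lo, hi = np.quantile(values, bounds)
    uniq = np.unique(values)
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        if not lo <= c <= hi:
            continue
        high = values > c
        if high.sum() < min_group or (~high).sum() < min_group:
            continue
        r = ll_logrank(times[high], times[~high], events[high], events[~high])
        if best is None or r.test_statistic > best[1]:
            best = (c, r.test_statistic)
    return best


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        steps = km.set_index("time")["survival"]
        assert list(steps.loc[[1, 2, 3, 4]]) == pytest.approx([0.75, 0.5, 0.25, 0.0])

    def test_censoring_keeps_curve_above_empirical(self):
        km = km_estimate([1, 2, 3, 4], [1, 0, 1, 0])
        assert km["survival"].iloc[-1] > 0.0


class TestLogrank:
    def test_identical_groups_score_zero(self):
        t = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
        e = np.ones(10, dtype=int)
        stat, p = logrank_statistic(t, e, np.arange(10) < 5)
        assert stat == pytest.approx(0.0, abs=1e-9) and p == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 60
            grp = rng.random(n) < 0.5
            t = rng.exponential(10, n) * np.where(grp, 0.5, 1.0)
            e = (rng.random(n) < 0.8).astype(int)
            stat, p = logrank_statistic(t, e, grp)
            r = ll_logrank(t[grp], t[~grp], e[grp], e[~grp])
            assert stat == pytest.approx(r.test_statistic, rel=1e-6)
            assert p == pytest.approx(r.p_value, rel=1e-6)

    def test_power_against_hazard_ratio_three(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(20):
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(1 / 3, 200)
            _, p = logrank_test(ta, np.ones(200, int), tb, np.ones(200, int))
            hits += p < 1e-3
        assert hits >= 19

    def test_all_censored_is_an_error(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_statistic([1, 2], [0, 0], [True, False])


class TestOptimalCutpoint:
    def test_constant_feature_has_no_admissible_cutoff(self):
        with pytest.raises(ValueError, match="no admissible cutoff"):
            optimal_cutpoint(np.ones(20), np.arange(20.0) + 1, np.ones(20, int))

    def test_perfectly_ordered_feature_splits_the_blocs(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.uniform(0, 1, 15), rng.uniform(5, 6, 15)])
        times = np.concatenate([rng.uniform(1, 5, 15), rng.uniform(20, 30, 15)])
        events = np.ones(30, dtype=int)
        cp = optimal_cutpoint(values, times, events)
        assert 1 < cp.cutoff < 5
        oracle = exhaustive_scan_oracle(values, times, events)
        assert cp.statistic == pytest.approx(oracle[1], rel=1e-6)

    def test_statistic_dominates_every_admissible_candidate(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 40
            values = rng.normal(0, 1, n)
            times = rng.exponential(10, n)
            events = (rng.random(n) < 0.7).astype(int)
            if events.sum() == 0:
                continue
            cp = optimal_cutpoint(values, times, events)
            oracle = exhaustive_scan_oracle(values, times, events)
            assert cp.statistic == pytest.approx(oracle[1], rel=1e-6)
            assert cp.cutoff == pytest.approx(oracle[0])

    def test_permutation_p_exceeds_naive_p_under_null(self):
        rng = np.random.default_rng(6)
        values = rng.normal(0, 1, 50)
        times = rng.exponential(10, 50)
        events = np.ones(50, dtype=int)
        cp = optimal_cutpoint(values, times, events, n_permutations=99, rng=rng)
        assert cp.selection_biased
        assert cp.p_permutation is not None and cp.p_permutation >= cp.p_value


class TestCox:
    def test_identical_survival_gives_unit_hazard(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(10, 200)
        e = np.ones(200, dtype=int)
        grp = np.arange(200) % 2 == 0
        cox = univariate_cox(grp, t, e)
        assert cox.ci_low <= 1.0 <= cox.ci_high
        assert abs(np.log(cox.hazard_ratio)) < 0.5

    def test_label_swap_inverts_the_hazard_ratio(self):
        rng = np.random.default_rng(8)
        grp = rng.random(150) < 0.5
        t = rng.exponential(1.0, 150) * np.where(grp, 0.4, 1.0)
        e = np.ones(150, dtype=int)
        a = univariate_cox(grp, t, e)
        b = univariate_cox(~grp, t, e)
        assert a.hazard_ratio == pytest.approx(1 / b.hazard_ratio, rel=1e-4)

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            univariate_cox([True, False], [1.0, 2.0], [0, 0])


class TestScreenAndClassifier:
    def test_screen_reports_hazard_table_columns(self):
        rng = np.random.default_rng(9)
        n = 60
        risk = rng.normal(0, 1, n)
        m = pd.DataFrame({"risky": risk, "noise": rng.normal(0, 1, n)},
                         index=[f"s{i}" for i in range(n)])
        t = rng.exponential(np.exp(-risk), n)
        e = np.ones(n, dtype=int)
        screen = survival_screen(m, t, e)
        assert {"hazard_ratio", "hr_ci_low", "hr_ci_high", "logrank_p"} <= set(screen.columns)
        assert screen.loc["risky", "logrank_p"] < 0.05
        assert screen.loc["risky", "hazard_ratio"] > 1.0

    def test_classifier_excludes_lost_to_followup(self):
        from ecckit.diagnostic import HarnessConfig

        rng = np.random.default_rng(10)
        n = 60
        X = pd.DataFrame(rng.normal(0, 1, (n, 5)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"f{i}" for i in range(5)])
        events = (rng.random(n) < 0.4).astype(float)
        clin = pd.DataFrame({
            "sample_id": X.index,
            "dfs_time": rng.exponential(10, n),
            "dfs_event": events,
        })
        clin.loc[:4, ["dfs_time", "dfs_event"]] = np.nan
        rep = prognostic_classifier(
            X, clin, HarnessConfig(seed=0, cv_folds=5, attribution_method="none")
        )
        assert rep["n_excluded_lost_to_followup"] == 5
        assert rep["n_train"] + rep["n_test"] == n - 5
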