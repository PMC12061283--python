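import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gliorisk as gr


def km_bruteforce(times, events):
    """Product-limit estimate by explicit risk-set enumeration."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = {}
    s = 1.0
    for t in sorted(set(times[events == 1])):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


def logrank_bruteforce(times, events, group):
    """Log-rank chi-square from the explicit risk-set table."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    g0 = np.unique(group)[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (group == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & (group == g0)).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


class TestRiskScore:
    def _bulk(self, values):
        return pd.DataFrame(
            {g: values for g in ("m1", "m2", "m3")},
            index=[f"s{i}" for i in range(len(values))],
        )

    def test_two_sample_scores(self):
        bulk = self._bulk([1.0, 10.0])
        score = gr.compute_risk_score(bulk, ["m1", "m2", "m3"])
        np.testing.assert_allclose(score.to_numpy(), [-1.0, 1.0])

    def test_mean_zero_unit_variance(self):
        rng = np.random.default_rng(0)
        bulk = pd.DataFrame(
            rng.lognormal(0, 1, size=(50, 3)), columns=["m1", "m2", "m3"]
        )
        score = gr.compute_risk_score(bulk, ["m1", "m2", "m3"])
        assert abs(score.mean()) < 1e-9
        assert score.std(ddof=0) == pytest.approx(1.0)

    def test_invariant_to_marker_rescaling(self):
        rng = np.random.default_rng(1)
        bulk = pd.DataFrame(
            rng.lognormal(2, 0.5, size=(30, 3)), columns=["m1", "m2", "m3"]
        )
        base = gr.compute_risk_score(bulk, ["m1", "m2", "m3"])
        scaled = bulk.copy()
        scaled["m2"] = scaled["m2"] * 250.0
        rescored = gr.compute_risk_score(scaled, ["m1", "m2", "m3"])
        # log1p is not exactly log, so the shift is absorbed only approximately
        np.testing.assert_allclose(
            base.to_numpy(), rescored.to_numpy(), atol=0.05
        )

    def test_missing_and_constant_markers_rejected(self):
        bulk = self._bulk([1.0, 2.0, 3.0])
        with pytest.raises(KeyError, match="m9"):
            gr.compute_risk_score(bulk, ["m1", "m9"])
        bulk["m1"] = 5.0
        with pytest.raises(ValueError, match="m1"):
            gr.compute_risk_score(bulk, ["m1", "m2"])


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = gr.km_estimate([5, 6, 7], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_all_events_product_limit(self):
        curve = gr.km_estimate([1, 2, 3], [1, 1, 1]).set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_censoring_removes_from_risk_set(self):
        curve = gr.km_estimate([1, 2, 3], [1, 0, 1]).set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gr.km_estimate([], [])

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = rng.integers(3, 12)
            times = rng.integers(1, 6, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            curve = gr.km_estimate(times, events).set_index("time")["survival"]
            for t, s in km_bruteforce(times, events).items():
                assert curve.loc[t] == pytest.approx(s, abs=1e-10)


class TestLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        group = ["a"] * 4 + ["b"] * 4
        stat, p = gr.logrank_test(times, events, group)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_no_events_anywhere(self):
        stat, p = gr.logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert (stat, p) == (0.0, 1.0)

    def test_worked_six_subject_example(self):
        """Hand-checkable risk-set table for 6 subjects."""
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 1, 0]
        group = ["a", "b", "a", "b", "a", "b"]
        stat, _ = gr.logrank_test(times, events, group)
        assert stat == pytest.approx(
            logrank_bruteforce(times, events, group), abs=1e-10
        )

    def test_exhaustive_small_configurations(self):
        """Implementation equals the explicit risk-set computation on every
        event/group configuration up to n = 8 (distinct times)."""
        checked = 0
        for n in (4, 6, 8):
            times = np.arange(1.0, n + 1)
            for events in itertools.product([0, 1], repeat=n):
                if sum(events) == 0:
                    continue
                group = np.array(["a", "b"] * (n // 2))
                stat, _ = gr.logrank_test(times, list(events), group)
                assert stat == pytest.approx(
                    logrank_bruteforce(times, events, group), abs=1e-8
                )
                checked += 1
        assert checked > 300

    def test_tied_times_match_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = 8
            times = rng.integers(1, 4, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            group = np.array(list("ab") * 4)
            if events.sum() == 0:
                continue
            stat, _ = gr.logrank_test(times, events, group)
            assert stat == pytest.approx(
                logrank_bruteforce(times, events, group), abs=1e-8
            )

    def test_chisquare_p_close_to_permutation_p(self):
        rng = np.random.default_rng(6)
        n = 100
        times = rng.exponential(100, n)
        events = rng.integers(0, 2, n)
        group = np.array(["a"] * 50 + ["b"] * 50)
        stat, p = gr.logrank_test(times, events, group)
        # the brute-force statistic (verified equal to the implementation
        # above) drives the permutation null
        perm_stats = [
            logrank_bruteforce(times, events, rng.permutation(group))
            for _ in range(2000)
        ]
        perm_p = np.mean(np.asarray(perm_stats) >= stat)
        assert p == pytest.approx(perm_p, abs=0.02)


class TestOptimalCutpoint:
    def _separated(self, n=40, seed=0):
        """Score separates an early-death from a late-death subgroup with
        non-overlapping survival times."""
        rng = np.random.default_rng(seed)
        score = np.concatenate(
            [rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)]
        )
        times = np.concatenate(
            [100.0 + np.arange(n // 2), 1.0 + np.arange(n // 2)]
        )
        events = np.ones(n, dtype=int)
        return score, times, events

    def test_recovers_median_split(self):
        score, times, events = self._separated()
        cut, groups = gr.optimal_cutpoint(score, times, events)
        n_low = (groups == "low").sum()
        assert abs(n_low - len(score) / 2) <= 1
        assert -2 < cut < 2

    def test_candidates_respect_quantile_bounds(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            score = rng.normal(size=30)
            times = rng.exponential(100, 30)
            events = rng.integers(0, 2, 30)
            if events.sum() < 2:
                continue
            cut, groups = gr.optimal_cutpoint(score, times, events)
            frac_low = (groups == "low").mean()
            assert np.ceil(0.1 * 30) / 30 <= frac_low <= np.floor(0.9 * 30) / 30

    def test_equals_exhaustive_scan(self):
        rng = np.random.default_rng(9)
        score = rng.normal(size=25)
        times = rng.exponential(50, 25)
        events = rng.integers(0, 2, 25)
        events[:5] = 1
        cut, _ = gr.optimal_cutpoint(score, times, events)
        best_p, best_c = np.inf, None
        for c in sorted(score):
            n_low = (score <= c).sum()
            if not (np.ceil(0.1 * 25) <= n_low <= np.floor(0.9 * 25)):
                continue
            _, p = gr.logrank_test(times, events, np.where(score > c, "h", "l"))
            if p < best_p:
                best_p, best_c = p, c
        assert cut == pytest.approx(best_c)

    def test_sign_reversal_mirrors_partition(self):
        score, times, events = self._separated(seed=5)
        cut, groups = gr.optimal_cutpoint(score, times, events)
        cut2, groups2 = gr.optimal_cutpoint(-score, times, events)
        # the same two subsets, with high/low labels swapped
        assert set(map(tuple, [np.flatnonzero(groups == "high")])) == set(
            map(tuple, [np.flatnonzero(groups2 == "low")])
        ) or np.array_equal(groups == "high", groups2 == "low")

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gr.optimal_cutpoint(np.ones(20), np.arange(1, 21.0), np.ones(20, int))


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.integers(0, 2, n)
        times = rng.exponential(1.0 / (0.01 * 2.0**x))
        cov = pd.DataFrame({"x": x.astype(float)})
        out = gr.cox_fit(cov.assign(z=rng.normal(size=n)), times, np.ones(n, int))
        assert 1.7 <= out.loc["x", "hr"] <= 2.3

    def test_constant_covariate_rejected(self):
        cov = pd.DataFrame({"x": np.ones(30), "y": np.arange(30.0)})
        with pytest.raises(ValueError, match="constant"):
            gr.cox_fit(cov, np.arange(1, 31.0), np.ones(30, int))


class TestCollinearity:
    def test_orthogonal_design_unit_vif(self):
        cov = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        out = gr.collinearity_check(cov)
        np.testing.assert_allclose(out["vif"], 1.0)
        np.testing.assert_allclose(out["tolerance"], 1.0)

    def test_duplicated_covariate_flagged_infinite(self):
        x = np.arange(10.0)
        out = gr.collinearity_check(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(out["vif"]).all()
        assert out["collinear"].all()

    def test_known_correlation_gives_closed_form_vif(self):
        rng = np.random.default_rng(11)
        n = 1000
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        out = gr.collinearity_check(pd.DataFrame({"a": a, "b": b}))
        assert out.loc["a", "vif"] == pytest.approx(1 / (1 - 0.81), abs=0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert gr.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert gr.roc_auc(np.ones(10), [0, 1] * 5) == pytest.approx(0.5)

    def test_equals_ranksum_estimator(self):
        rng = np.random.default_rng(12)
        score = rng.normal(size=60)
        status = rng.integers(0, 2, 60)
        pos = score[status == 1]
        neg = score[status == 0]
        bruteforce = np.mean(
            [(p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg]
        )
        assert gr.roc_auc(score, status) == pytest.approx(bruteforce)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gr.roc_auc([1, 2, 3], [1, 1, 1])


class TestRiskStratifier:
    def test_fit_predict_roundtrip(self, bulk_cohorts, pipeline_result):
        bulk = bulk_cohorts["c2"]
        model = pipeline_result.risk_models["c2"]
        est = gr.RiskStratifier(model.marker_genes).fit(
            bulk.expression, bulk.clinical
        )
        pred = est.predict(bulk.expression)
        assert (pred == est.model_.group).all()
        assert est.model_.cutpoint == model.cutpoint
        # cutpoint lies inside the score's 10th-90th percentile band
        s = est.model_.score
        assert s.quantile(0.1) <= est.model_.cutpoint <= s.quantile(0.9)
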