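import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathsurv.containers import SurvivalTable
from pathsurv.metrics import (MetricResult, bootstrap_metric_ci,
                              brier_score_ipcw, censoring_model,
                              concordance_index, corrected_resampled_ttest,
                              integrated_brier_score, km_estimator,
                              risk_group_split)

from conftest import make_survival
from oracles import brier_oracle, cindex_oracle, km_oracle


def surv_of(times, events):
    return SurvivalTable([f"s{i}" for i in range(len(times))],
                         np.asarray(times, float), np.asarray(events))


class TestKaplanMeier:
    def test_no_events_flat_one(self):
        sf = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(sf([0.5, 2.5, 10.0]) == 1.0)

    def test_all_events_closed_form(self):
        sf = km_estimator([1.0, 2.0, 3.0], [1, 1, 1])
        assert sf(1.0) == pytest.approx(2 / 3)
        assert sf(2.0) == pytest.approx(1 / 3)
        assert sf(3.0) == pytest.approx(0.0)

    def test_censoring_handled_like_product_limit(self):
        times = [1.0, 1.5, 3.0]
        events = [1, 0, 1]
        sf = km_estimator(times, events)
        oracle = km_oracle(times, events)
        for t in (0.5, 1.0, 1.6, 3.0, 4.0):
            assert sf(t) == pytest.approx(oracle(t), abs=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(0)
        t, e = make_survival(rng, 60)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        sf = km_estimator(t, e)
        grid = np.linspace(0, t.max(), 17)
        ours = sf(grid)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            km_estimator([], [])


class TestBrierScore:
    def test_perfect_predictions_zero(self):
        sv = surv_of([1, 2, 8, 9], [1, 1, 1, 1])
        pi = np.array([0.0, 0.0, 1.0, 1.0])
        assert brier_score_ipcw(pi, sv, t_star=5.0) == pytest.approx(0.0)

    def test_constant_half_gives_quarter(self):
        sv = surv_of([1, 2, 8, 9], [1, 1, 1, 1])
        pi = np.full(4, 0.5)
        assert brier_score_ipcw(pi, sv, t_star=5.0) == pytest.approx(0.25)

    def test_censored_case_matches_term_enumeration(self):
        times = [2.0, 4.0, 6.0, 9.0]
        events = [1, 0, 1, 1]
        sv = surv_of(times, events)
        pi = np.array([0.9, 0.6, 0.4, 0.2])
        ours = brier_score_ipcw(pi, sv, t_star=5.0)
        oracle = brier_oracle(pi, times, events, t_star=5.0)
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_reduces_to_plain_brier_without_censoring(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 10, 20)
        e = np.ones(20, dtype=int)
        pi = rng.uniform(size=20)
        sv = surv_of(t, e)
        t_star = 5.0
        plain = np.mean(((t > t_star).astype(float) - pi) ** 2)
        assert brier_score_ipcw(pi, sv, t_star) == pytest.approx(plain, abs=1e-12)

    def test_censored_before_tstar_has_zero_weight(self):
        sv = surv_of([2.0, 4.0, 6.0, 9.0], [1, 0, 1, 1])
        pi_a = np.array([0.9, 0.6, 0.4, 0.2])
        pi_b = pi_a.copy()
        pi_b[1] = 0.01  # subject censored at 4 < t* = 5 must not matter
        a = brier_score_ipcw(pi_a, sv, t_star=5.0)
        b = brier_score_ipcw(pi_b, sv, t_star=5.0)
        assert a == b


class TestIntegratedBrier:
    def test_constant_bs_integrates_to_itself(self):
        sv = surv_of([2, 4, 6, 8], [1, 1, 1, 1])
        # pi = 0.5 for everyone: BS(t) = 0.25 at every grid time
        ibs = integrated_brier_score(lambda ts: np.full((4, len(ts)), 0.5), sv)
        assert ibs == pytest.approx(0.25)

    def test_perfect_predictions_zero(self):
        sv = surv_of([1, 3, 5, 7], [1, 1, 1, 1])

        def pi(ts):
            return (sv.time[:, None] > ts[None, :]).astype(float)

        assert integrated_brier_score(pi, sv) == pytest.approx(0.0)

    def test_hand_integrated_piecewise_value(self):
        # 5 subjects, no censoring, constant pi = 0.4: BS(t) is piecewise
        # constant between event times; integrate by hand with trapezoids
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sv = surv_of(times, [1, 1, 1, 1, 1])
        pi_val = 0.4

        def bs(t):
            alive = (times > t).astype(float)
            return np.mean((alive - pi_val) ** 2)

        grid = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        hand = np.trapezoid([bs(t) for t in grid], grid) / 5.0
        ibs = integrated_brier_score(
            lambda ts: np.full((5, len(ts)), pi_val), sv)
        assert ibs == pytest.approx(hand, abs=1e-12)


class TestConcordance:
    def test_perfect_ordering(self):
        sv = surv_of([1, 2, 3], [1, 1, 1])
        assert concordance_index([3, 2, 1], sv).estimate == 1.0

    def test_pair_exclusion_rules(self):
        # i event at 2 vs j censored at 1: unusable; censored at 3: usable
        sv = surv_of([2, 1], [1, 0])
        with pytest.raises(ValueError, match="usable"):
            concordance_index([1.0, 0.0], sv)
        sv2 = surv_of([2, 3], [1, 0])
        r = concordance_index([1.0, 0.0], sv2)
        assert r.n_pairs == 1 and r.estimate == 1.0

    def test_all_ties_half(self):
        sv = surv_of([1, 2, 3, 4], [1, 1, 1, 1])
        assert concordance_index([5, 5, 5, 5], sv).estimate == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        t, e = make_survival(rng, 40)
        sv = surv_of(t, e)
        risk = rng.standard_normal(40)
        a = concordance_index(risk, sv).estimate
        b = concordance_index(np.exp(2 * risk) + 3, sv).estimate
        assert a == b

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            t = rng.integers(1, 6, n).astype(float)  # force some ties
            e = rng.integers(0, 2, n)
            risk = rng.integers(-2, 3, n).astype(float)
            expect, pairs = cindex_oracle(risk, t, e)
            if expect is None:
                with pytest.raises(ValueError):
                    concordance_index(risk, surv_of(t, e))
            else:
                got = concordance_index(risk, surv_of(t, e))
                assert got.estimate == pytest.approx(expect, abs=1e-12)
                assert got.n_pairs == pairs


class TestCorrectedTTest:
    def test_all_zero_diffs(self):
        t, p = corrected_resampled_ttest(np.zeros(10), 70, 30)
        assert t == 0.0 and p == 1.0

    def test_correction_factor_algebra(self):
        rng = np.random.default_rng(4)
        d = rng.standard_normal(100)
        j = len(d)
        t_corr, _ = corrected_resampled_ttest(d, 70, 30)
        t_naive = d.mean() / np.sqrt(d.var(ddof=1) / j)
        factor = np.sqrt((1 / j) / (1 / j + 30 / 70))
        assert t_corr == pytest.approx(t_naive * factor, rel=1e-12)

    def test_zero_variance_nonzero_mean(self):
        t, p = corrected_resampled_ttest(np.full(5, 0.2), 70, 30)
        assert p == 0.0 and t == np.inf

    def test_needs_two_diffs(self):
        with pytest.raises(ValueError):
            corrected_resampled_ttest([0.1], 70, 30)


class TestBootstrap:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        t, e = make_survival(rng, 50)
        sv = surv_of(t, e)
        risk = rng.standard_normal(50)
        fn = lambda r, s: concordance_index(r, s).estimate
        a = bootstrap_metric_ci(fn, risk, sv, B=50, seed=9)
        b = bootstrap_metric_ci(fn, risk, sv, B=50, seed=9)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_degenerate_metric_point_ci(self):
        rng = np.random.default_rng(6)
        t, e = make_survival(rng, 30)
        sv = surv_of(t, e)
        fn = lambda r, s: 0.7
        res = bootstrap_metric_ci(fn, np.zeros(30), sv, B=20, seed=0)
        assert res.ci_lower == res.ci_upper == res.estimate == 0.7

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(7)
        t, e = make_survival(rng, 80, signal=rng.standard_normal(80))
        sv = surv_of(t, e)
        risk = rng.standard_normal(80)
        fn = lambda r, s: concordance_index(r, s).estimate
        res = bootstrap_metric_ci(fn, risk, sv, B=100, seed=1)
        assert res.ci_lower <= res.estimate <= res.ci_upper


class TestRiskGroups:
    def test_median_split(self):
        high = risk_group_split(np.array([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_array_equal(high, [False, False, True, True])

    def test_odd_n_median_goes_low(self):
        high = risk_group_split(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(high, [False, False, True])

    def test_identical_risks_error(self):
        with pytest.raises(ValueError, match="identical"):
            risk_group_split(np.ones(4))

    def test_high_risk_group_has_worse_survival(self):
        rng = np.random.default_rng(8)
        n = 400
        lp = rng.standard_normal(n) * 1.5
        t, e = make_survival(rng, n, lp)
        sv = surv_of(t, e)
        high, curves = risk_group_split(lp, sv)
        t_med = np.median(t)
        assert curves["high"](t_med) < curves["low"](t_med)


@settings(max_examples=40, derandomize=True)
@given(st.lists(
    st.tuples(st.floats(0.0, 200.0, allow_nan=False, allow_infinity=False),
              st.booleans()),
    min_size=1, max_size=12))
def test_km_is_a_proper_survival_function(obs):
    """Product-limit output is a non-increasing step function in [0, 1]
    that starts at 1 before the first event."""
    times = np.array([t for t, _ in obs])
    events = np.array([int(e) for _, e in obs])
    sf = km_estimator(times, events)
    grid = np.sort(np.concatenate([[0.0], times, times + 0.5]))
    vals = sf(grid)
    assert np.all((vals >= 0) & (vals <= 1))
    assert np.all(np.diff(vals) <= 1e-15)
    first_event = times[events == 1].min() if events.any() else np.inf
    assert np.all(vals[grid < first_event] == 1.0)


@settings(max_examples=40, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 5.0))
def test_cindex_invariant_under_increasing_transforms(seed, scale):
    """Any strictly increasing transform of the risk scores leaves the
    concordance index unchanged."""
    rng = np.random.default_rng(seed)
    n = 25
    t, e = make_survival(rng, n)
    if e.sum() == 0:
        return
    risk = rng.standard_normal(n)
    sv = surv_of(t, e)
    base = concordance_index(risk, sv).estimate
    assert concordance_index(scale * risk + 1.0, sv).estimate == base
    assert concordance_index(np.tanh(risk), sv).estimate == base


def test_metric_result_ci_must_bracket():
    with pytest.raises(ValueError):
        MetricResult("x", 0.5, ci_lower=0.6, ci_upper=0.7)


def test_censoring_model_is_reverse_km():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 0]
    g = censoring_model(surv_of(t, e))
    o = km_oracle(t, [1 - x for x in e])
    for q in (0.5, 2.0, 3.5, 4.0):
        assert g(q) == pytest.approx(o(q), abs=1e-12)
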