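import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize

from protect import baselines as bl
from protect.simulate import generate_cohort, nsclc_like_params


def _neg_log_partial_likelihood(beta, x, times, events):
    """Brute-force Cox partial likelihood by explicit risk-set enumeration
    (Breslow form; the fixtures below have no tied event times, where
    Breslow and Efron coincide)."""
    eta = x @ beta
    out = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        out -= eta[i] - np.log(np.exp(eta[risk]).sum())
    return out


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood_on_tiny_fixture(self):
        cohort = pd.DataFrame(
            {
                "treatment": [1, 0, 1, 0, 1],
                "age_z": [0.3, -1.2, 0.8, 0.1, -0.5],
                "time": [1.0, 2.0, 3.0, 4.0, 5.0],
                "event": [1, 1, 0, 1, 1],
                "histology": ["adeno"] * 5,
            }
        )
        est = bl.cox_fit(cohort, ["age_z"])
        x = cohort[["treatment", "age_z"]].to_numpy(float)
        res = minimize(
            _neg_log_partial_likelihood,
            np.zeros(2),
            args=(x, cohort["time"].to_numpy(), cohort["event"].to_numpy()),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        assert np.log(est.hr) == pytest.approx(res.x[0], abs=1e-6)
        assert est.coefficients["age_z"] == pytest.approx(res.x[1], abs=1e-6)

    def test_null_two_group_exponential_covers_one(self):
        rng = np.random.default_rng(12)
        n = 5000
        a = rng.integers(0, 2, n)
        t = rng.exponential(1.0, n)
        c = rng.uniform(0.5, 4.0, n)
        cohort = pd.DataFrame(
            {
                "treatment": a,
                "time": np.minimum(t, c),
                "event": (t <= c).astype(int),
                "histology": "adeno",
            }
        )
        est = bl.cox_fit(cohort, [])
        assert est.ci_low < 1.0 < est.ci_high

    def test_zero_variance_covariate_dropped_with_warning(self):
        cohort, _ = generate_cohort(nsclc_like_params(), 200, seed=1)
        cohort["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            est = bl.cox_fit(cohort, ["flat", "age_z"])
        assert "flat" not in est.coefficients.index

    def test_no_events_rejected(self):
        cohort = pd.DataFrame(
            {"treatment": [0, 1], "time": [1.0, 2.0], "event": [0, 0], "histology": "adeno"}
        )
        with pytest.raises(bl.BaselinesError):
            bl.cox_fit(cohort, [])


COVS = ["age_z", "histology", "weight_loss", "stage_iiib_c", "ps_geq1", "egfr_lt60"]


class TestIpwCox:
    def test_intercept_only_propensity_equals_unadjusted(self, small_cohort):
        cohort, _ = small_cohort
        ipw = bl.ipw_cox(cohort, [])
        plain = bl.cox_fit(cohort, [])
        assert ipw.hr == pytest.approx(plain.hr, rel=1e-6)

    def test_stabilized_weights_sum_to_arm_sizes(self, small_cohort):
        cohort, _ = small_cohort
        ps = bl.estimate_propensity(cohort, COVS)
        a = cohort["treatment"].to_numpy(float)
        w = np.where(a == 1, a.mean() / ps, (1 - a.mean()) / (1 - ps))
        assert w[a == 1].sum() == pytest.approx((a == 1).sum(), rel=0.1)
        assert w[a == 0].sum() == pytest.approx((a == 0).sum(), rel=0.1)

    def test_extreme_propensities_advise_trimming(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.standard_normal(n)
        cohort = pd.DataFrame(
            {
                "treatment": (x > 0).astype(int),  # perfectly separable
                "age_z": x,
                "time": rng.exponential(1, n) + 0.01,
                "event": 1,
                "histology": "adeno",
            }
        )
        with pytest.raises(bl.BaselinesError, match="trim"):
            bl.ipw_cox(cohort, ["age_z"])

    def test_reduces_observed_confounding_bias(self):
        """With a single *observed* binary confounder, IPW should land
        closer to the null truth than the unadjusted estimate in most
        replicates."""
        rng = np.random.default_rng(44)
        wins = 0
        for _ in range(10):
            n = 2000
            x = rng.integers(0, 2, n)
            a = (rng.random(n) < 1 / (1 + np.exp(-(1.2 * x - 0.6)))).astype(int)
            t = rng.exponential(np.exp(-0.8 * x))
            c = rng.uniform(0.2, 3.0, n)
            cohort = pd.DataFrame(
                {
                    "treatment": a,
                    "x": x.astype(float),
                    "time": np.maximum(np.minimum(t, c), 1e-6),
                    "event": (t <= c).astype(int),
                    "histology": "adeno",
                }
            )
            unadj = abs(np.log(bl.cox_fit(cohort, []).hr))
            ipw = abs(np.log(bl.ipw_cox(cohort, ["x"]).hr))
            wins += ipw < unadj
        assert wins >= 8


def _enumerate_c_index(scores, times, events):
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    return num / den


class TestHarrellC:
    def test_perfect_ranking(self):
        assert bl.harrell_c([3, 2, 1], [1, 2, 3], [1, 1, 1]) == 1.0

    def test_two_of_three_pairs(self):
        assert bl.harrell_c([2, 3, 1], [1, 2, 3], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_all_ties_give_half(self):
        assert bl.harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 1]) == 0.5

    def test_matches_exhaustive_enumeration_with_censoring(self):
        rng = np.random.default_rng(9)
        n = 200
        scores = np.round(rng.normal(size=n), 1)  # induce score ties
        times = rng.exponential(1, n)
        events = rng.integers(0, 2, n)
        events[np.argmax(times)] = 1
        expected = _enumerate_c_index(scores, times, events)
        assert bl.harrell_c(scores, times, events) == pytest.approx(expected, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(bl.BaselinesError):
            bl.harrell_c([1, 2], [1.0, 2.0], [0, 0])


class TestAuc:
    def test_perfect_separation(self):
        assert bl.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_four_point_fixture(self):
        assert bl.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_independent_scores_are_uninformative(self):
        rng = np.random.default_rng(10)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert bl.auc(scores, labels) == pytest.approx(0.5, abs=3 * 0.6 / np.sqrt(2500))

    def test_single_class_rejected(self):
        with pytest.raises(bl.BaselinesError):
            bl.auc([0.1, 0.2], [1, 1])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 1)), min_size=4, max_size=60
        ).filter(lambda xs: len({l for _, l in xs}) == 2)
    )
    def test_equals_pair_enumeration(self, pairs):
        scores = np.array([s for s, _ in pairs], float)
        labels = np.array([l for _, l in pairs], float)
        num = den = 0.0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                den += 1
                num += 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
        assert bl.auc(scores, labels) == pytest.approx(num / den, abs=1e-12)


class TestSwitchCheck:
    def test_frailty_driven_switching_is_detected(self, fitted, small_cohort):
        cohort, _ = small_cohort  # switch simulated as logistic in -U_f
        assert bl.switch_check(fitted, cohort, arm=1) > 0.55

    def test_random_switching_is_uninformative(self, fitted, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(0)
        shuffled = cohort.assign(switch=rng.permutation(cohort["switch"].to_numpy()))
        assert 0.4 < bl.switch_check(fitted, shuffled, arm=1) < 0.6

    def test_sign_flip_mirrors_auc(self, fitted, small_cohort):
        from protect.inference import posterior_fitness

        cohort, _ = small_cohort
        sub = cohort[cohort["treatment"] == 1]
        fitness = posterior_fitness(fitted, sub).mean(0)
        auc_neg = bl.auc(-fitness, sub["switch"])
        auc_pos = bl.auc(fitness, sub["switch"])
        assert auc_neg == pytest.approx(1.0 - auc_pos, abs=1e-12)

    def test_missing_switch_column_rejected(self, fitted, default_params):
        cohort, _ = generate_cohort(default_params, 50, seed=2)
        with pytest.raises(bl.BaselinesError):
            bl.switch_check(fitted, cohort)


def test_comparison_table_shape(small_cohort):
    cohort, _ = small_cohort
    rows = [bl.cox_fit(cohort, []), bl.cox_fit(cohort, COVS)]
    table = bl.comparison_table(rows)
    assert list(table["estimator"]) == ["unadjusted Cox", "adjusted Cox"]
    assert (table["ci_low"] <= table["hr"]).all()
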