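import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from scipy import stats

from protect.params import ParamSet
from protect.simulate import (
    SimulationError,
    generate_cohort,
    inject_missingness,
    nsclc_like_params,
    true_effects,
)


class TestMargins:
    def test_neutral_parameters_give_half_prevalences(self):
        params = ParamSet({"weibull_shape": 1.0})
        cohort, _ = generate_cohort(params, 20000, seed=3)
        se3 = 3 * 0.5 / np.sqrt(len(cohort))
        for col in ("ps_geq1", "egfr_lt60", "weight_loss", "stage_iiib_c", "treatment"):
            assert cohort[col].mean() == pytest.approx(0.5, abs=se3)

    def test_fitness_only_treatment_is_balanced_by_symmetry(self):
        """With logit(A) = U_f and U_f symmetric about zero, the marginal
        treatment probability is the logistic-normal integral = 1/2."""
        params = ParamSet({"treatment_fitness": 1.0, "weibull_shape": 1.0})
        cohort, _ = generate_cohort(params, 20000, seed=4)
        assert cohort["treatment"].mean() == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(20000))

    def test_nsclc_like_margins(self, default_params):
        cohort, _ = generate_cohort(default_params, 40000, seed=6)
        targets = {
            "ps_geq1": 0.455, "egfr_lt60": 0.10, "weight_loss": 0.45,
            "stage_iiib_c": 0.46, "treatment": 0.444, "event": 0.70,
        }
        for col, target in targets.items():
            assert cohort[col].mean() == pytest.approx(target, abs=0.015)

    def test_adverse_proxy_marks_higher_event_risk(self):
        """With fitness lowering the hazard and raising PS >= 1 via the
        proxy link, PS >= 1 must associate with death at fixed treatment
        (Monte-Carlo oracle at large n)."""
        params = nsclc_like_params(outcome_fitness=-0.5, ps_geq1_loading=1.5)
        cohort, _ = generate_cohort(params, 200000, seed=7)
        for arm in (0, 1):
            sub = cohort[cohort["treatment"] == arm]
            p1 = sub.loc[sub["ps_geq1"] == 1, "event"].mean()
            p0 = sub.loc[sub["ps_geq1"] == 0, "event"].mean()
            assert p1 > p0


def test_same_seed_reproduces_cohort_bitwise(default_params):
    a, ta = generate_cohort(default_params, 300, seed=42, switch=(-0.5, 1.0))
    b, tb = generate_cohort(default_params, 300, seed=42, switch=(-0.5, 1.0))
    pd.testing.assert_frame_equal(a, b)
    np.testing.assert_array_equal(ta.latents, tb.latents)


def test_zero_fitness_edges_make_treatment_independent_of_proxies():
    params = nsclc_like_params(
        ps_geq1_loading=1e-12, egfr_lt60_loading=1e-12, treatment_fitness=0.0
    )
    cohort, _ = generate_cohort(params, 20000, seed=8)
    for proxy in ("ps_geq1", "egfr_lt60"):
        table = pd.crosstab(cohort[proxy], cohort["treatment"])
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01


def test_kaplan_meier_matches_closed_form_weibull():
    params = ParamSet({"outcome_intercept": -0.7, "weibull_shape": 1.3})
    cohort, _ = generate_cohort(params, 8000, seed=9)
    km = KaplanMeierFitter().fit(cohort["time"], cohort["event"])
    grid = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    est = km.survival_function_at_times(grid).to_numpy()
    expected = np.exp(-(grid**1.3) * np.exp(-0.7))
    np.testing.assert_allclose(est, expected, atol=0.02)


def test_invalid_inputs_rejected(default_params):
    with pytest.raises(SimulationError):
        generate_cohort(default_params, 0, seed=1)
    with pytest.raises(SimulationError):
        generate_cohort(default_params, 10, censoring=(2.0, 1.0), seed=1)
    with pytest.raises(SimulationError):
        nsclc_like_params(not_a_parameter=1.0)


class TestTrueEffects:
    def test_homogeneous_effect(self, default_params):
        params = nsclc_like_params(
            outcome_treatment=-0.4,
            interaction_age_z=0.0, interaction_stage_iiib_c=0.0,
            interaction_weight_loss=0.0, interaction_hist_squamous=0.0,
            interaction_hist_other=0.0, interaction_fitness=0.0,
        )
        cohort, truth = generate_cohort(params, 200, seed=10)
        ate, ite = true_effects(truth, cohort)
        np.testing.assert_allclose(ite, -0.4)
        assert ate == pytest.approx(-0.4)

    def test_weight_loss_modifier_shifts_ite(self):
        params = nsclc_like_params(
            outcome_treatment=-0.4, interaction_weight_loss=0.3,
            interaction_age_z=0.0, interaction_stage_iiib_c=0.0,
            interaction_hist_squamous=0.0, interaction_hist_other=0.0,
            interaction_fitness=0.0,
        )
        cohort, truth = generate_cohort(params, 500, seed=11)
        _, ite = true_effects(truth, cohort)
        wl = cohort["weight_loss"].to_numpy() == 1
        np.testing.assert_allclose(ite[wl], -0.1)
        np.testing.assert_allclose(ite[~wl], -0.4)

    def test_mean_equals_recorded_truth(self, default_params):
        cohort, truth = generate_cohort(default_params, 300, seed=12)
        ate, ite = true_effects(truth, cohort)
        assert ate == pytest.approx(truth.true_ate_loghr)
        np.testing.assert_allclose(ite, truth.true_ite_loghr)


class TestMissingness:
    def test_mcar_rate_zero_is_identity(self, default_params):
        cohort, _ = generate_cohort(default_params, 200, seed=13)
        out = inject_missingness(cohort, "mcar", rate=0.0, seed=1)
        pd.testing.assert_frame_equal(out, cohort)

    def test_mcar_rate_matches_binomial(self, default_params):
        cohort, _ = generate_cohort(default_params, 10000, seed=14)
        out = inject_missingness(cohort, "mcar", rate=0.1, seed=2)
        frac = out["weight_loss"].isna().mean()
        assert frac == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / 10000))

    def test_mnar_never_blanks_present_weight_loss_at_extreme(self, default_params):
        """The 'always observed if present' extreme: every missing value
        must come from a patient without weight loss."""
        cohort, _ = generate_cohort(default_params, 5000, seed=15)
        out = inject_missingness(
            cohort, "mnar_weightloss",
            p_miss_given_absent=0.4, p_miss_given_present=0.0, seed=3,
        )
        missing = out["weight_loss"].isna()
        assert missing.sum() > 0
        assert (cohort.loc[missing, "weight_loss"] == 0).all()

    def test_unknown_mechanism_rejected(self, default_params):
        cohort, _ = generate_cohort(default_params, 50, seed=16)
        with pytest.raises(SimulationError, match="unknown"):
            inject_missingness(cohort, "at_random_ish", rate=0.1)
        with pytest.raises(SimulationError):
            inject_missingness(
                cohort, "mnar_weightloss",
                p_miss_given_absent=0.1, p_miss_given_present=0.4,
            )
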