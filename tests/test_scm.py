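import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from protect.params import ParamSet, PriorSpec
from protect.scm import SCMError, linear_predictor, log_joint, log_prior, survival_logdensity
from protect.simulate import generate_cohort, nsclc_like_params


class TestLinearPredictor:
    def test_intercept_only(self, design):
        params = ParamSet({"treatment_intercept": 1.5})
        lp = linear_predictor(
            params,
            "treatment",
            {
                "fitness": 0.0, "age_z": 0.0, "stage_iiib_c": 0.0,
                "weight_loss": 0.0, "histology": "adeno",
            },
            design,
        )
        assert lp == pytest.approx(1.5)

    def test_fitness_proxy_is_adverse_coded(self, design):
        """Fitter patients must have a lower probability of PS >= 1: the
        loading enters the proxy logit with a minus sign."""
        params = ParamSet({"ps_geq1_intercept": 0.0, "ps_geq1_loading": 2.0})
        assert linear_predictor(params, "ps_geq1", {"fitness": 1.0}, design) == pytest.approx(-2.0)

    def test_outcome_includes_treatment_interactions(self, design):
        params = ParamSet({"outcome_treatment": -0.4, "interaction_weight_loss": 0.3})
        values = {
            "treatment": 1.0, "fitness": 0.0, "behavior": 0.0, "age_z": 0.0,
            "stage_iiib_c": 0.0, "weight_loss": 1.0, "histology": "adeno",
        }
        assert linear_predictor(params, "survival", values, design) == pytest.approx(-0.1)

    def test_missing_parent_names_node_and_parent(self, design):
        with pytest.raises(SCMError, match="ps_geq1.*fitness"):
            linear_predictor(ParamSet({}), "ps_geq1", {}, design)


class TestSurvivalLogDensity:
    def test_exponential_event(self):
        assert survival_logdensity(ParamSet({"weibull_shape": 1.0}), 0.0, 2.0, 1) == pytest.approx(-2.0)

    def test_exponential_censored(self):
        assert survival_logdensity(ParamSet({"weibull_shape": 1.0}), 0.0, 1.0, 0) == pytest.approx(-1.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(SCMError):
            survival_logdensity(ParamSet({"weibull_shape": 1.0}), 0.0, 0.0, 1)

    def test_matches_numerically_integrated_cumulative_hazard(self):
        """log f(t) = log h(t) - integral of the hazard up to t, with the
        integral done by quadrature instead of the closed form."""
        k, eta, t = 1.5, 0.2, 0.8
        params = ParamSet({"weibull_shape": k})
        hazard = lambda s: k * s ** (k - 1.0) * np.exp(eta)
        cumhaz, _ = integrate.quad(hazard, 0.0, t)
        expected = np.log(hazard(t)) - cumhaz
        assert survival_logdensity(params, eta, t, 1) == pytest.approx(expected, abs=1e-6)

    @given(
        eta=st.floats(-2, 2),
        time=st.floats(0.01, 20.0),
        event=st.integers(0, 1),
    )
    def test_shape_one_equals_exponential_loglik(self, eta, time, event):
        params = ParamSet({"weibull_shape": 1.0})
        rate = np.exp(eta)
        expected = event * np.log(rate) - rate * time
        assert survival_logdensity(params, eta, time, event) == pytest.approx(expected, rel=1e-12)


def _brute_force_log_joint(params, cohort, latents, include_prior=True):
    """Independent per-node evaluator with explicit formulas and scipy
    densities (no shared code with the implementation)."""
    g = params.get
    total = 0.0
    for i, row in enumerate(cohort.to_dict("records")):
        uf, ub = latents[i]
        total += stats.norm.logpdf(ub)
        total += stats.norm.logpdf(uf, loc=g("alpha") * row["age_z"])

        def bern(y, lp):
            return y * lp - np.log1p(np.exp(lp))

        total += bern(row["ps_geq1"], g("ps_geq1_intercept") - g("ps_geq1_loading") * uf)
        total += bern(row["egfr_lt60"], g("egfr_lt60_intercept") - g("egfr_lt60_loading") * uf)
        total += bern(row["weight_loss"], g("weight_loss_intercept") + g("weight_loss_loading") * ub)
        total += bern(row["stage_iiib_c"], g("stage_iiib_c_intercept") + g("stage_iiib_c_loading") * ub)
        logits = np.array(
            [
                0.0,
                g("histology_squamous_intercept") + g("histology_squamous_loading") * ub,
                g("histology_other_intercept") + g("histology_other_loading") * ub,
            ]
        )
        level = {"adeno": 0, "squamous": 1, "other": 2}[row["histology"]]
        total += logits[level] - np.log(np.exp(logits).sum())
        sq, ot = float(row["histology"] == "squamous"), float(row["histology"] == "other")
        lp_a = (
            g("treatment_intercept") + g("treatment_fitness") * uf
            + g("treatment_age_z") * row["age_z"]
            + g("treatment_stage_iiib_c") * row["stage_iiib_c"]
            + g("treatment_weight_loss") * row["weight_loss"]
            + g("treatment_hist_squamous") * sq + g("treatment_hist_other") * ot
        )
        total += bern(row["treatment"], lp_a)
        eta = (
            g("outcome_intercept") + g("outcome_treatment") * row["treatment"]
            + g("outcome_fitness") * uf + g("outcome_behavior") * ub
            + g("outcome_age_z") * row["age_z"]
            + g("outcome_stage_iiib_c") * row["stage_iiib_c"]
            + g("outcome_weight_loss") * row["weight_loss"]
            + g("outcome_hist_squamous") * sq + g("outcome_hist_other") * ot
            + row["treatment"]
            * (
                g("interaction_age_z") * row["age_z"]
                + g("interaction_stage_iiib_c") * row["stage_iiib_c"]
                + g("interaction_weight_loss") * row["weight_loss"]
                + g("interaction_hist_squamous") * sq
                + g("interaction_hist_other") * ot
                + g("interaction_fitness") * uf
            )
        )
        k = g("weibull_shape", 1.0)
        t = row["time"]
        total += row["event"] * (np.log(k) + (k - 1) * np.log(t) + eta) - t**k * np.exp(eta)
    if include_prior:
        pr = PriorSpec()
        for name in params:
            val = params[name]
            if name == "weibull_shape":
                total += stats.halfnorm.logpdf(val, scale=pr.scale_shape)
            elif name.endswith("_loading") and not name.startswith("histology"):
                total += stats.halfnorm.logpdf(val, scale=pr.scale_loading)
            else:
                total += stats.norm.logpdf(val, scale=pr.scale_coef)
    return total


def _three_patient_fixture():
    return pd.DataFrame(
        {
            "age_z": [0.5, -1.0, 0.0],
            "ps_geq1": [1.0, 0.0, 0.5],
            "egfr_lt60": [0.0, 1.0, 0.0],
            "weight_loss": [1.0, 0.0, 1.0],
            "histology": ["adeno", "squamous", "other"],
            "stage_iiib_c": [0.0, 1.0, 1.0],
            "treatment": [1, 0, 1],
            "time": [1.2, 0.4, 3.3],
            "event": [1, 1, 0],
        }
    )


class TestLogJoint:
    def test_neutral_parameters_give_half_probabilities(self, dag, design):
        """At all-zero coefficients every binary node contributes log(1/2)
        and histology log(1/3)."""
        cohort = _three_patient_fixture().iloc[[0]].assign(
            age_z=0.0, ps_geq1=1.0, weight_loss=0.0, histology="adeno",
            stage_iiib_c=1.0, time=1.0, event=0,
        )
        params = ParamSet({"weibull_shape": 1.0})
        value = log_joint(params, cohort, np.zeros((1, 2)), dag, include_prior=False)
        expected = (
            2 * stats.norm.logpdf(0.0)  # both latents at their mode
            + 5 * np.log(0.5)  # four binary proxies + treatment
            + np.log(1.0 / 3.0)  # histology
            - 1.0  # exponential survival, censored at t = 1
        )
        assert value == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_per_node_evaluator(self, dag):
        rng = np.random.default_rng(3)
        names = nsclc_like_params().as_dict()
        params = ParamSet(
            {k: (abs(rng.normal()) if k == "weibull_shape" else rng.normal(0, 0.5)) for k in names}
        )
        cohort = _three_patient_fixture()
        latents = rng.normal(size=(3, 2))
        ours = log_joint(params, cohort, latents, dag)
        brute = _brute_force_log_joint(params, cohort, latents)
        assert ours == pytest.approx(brute, rel=1e-10)

    def test_additive_over_disjoint_cohorts(self, dag, default_params):
        cohort, truth = generate_cohort(default_params, 8, seed=5)
        lat = truth.latents
        whole = log_joint(default_params, cohort, lat, dag, include_prior=False)
        first = log_joint(default_params, cohort.iloc[:3], lat[:3], dag, include_prior=False)
        rest = log_joint(default_params, cohort.iloc[3:], lat[3:], dag, include_prior=False)
        assert whole == pytest.approx(first + rest, rel=1e-12)

    def test_finite_for_random_parameters(self, dag):
        rng = np.random.default_rng(9)
        cohort = _three_patient_fixture()
        for _ in range(5):
            params = ParamSet(
                {
                    k: (abs(rng.normal()) + 0.1 if k == "weibull_shape" else rng.normal(0, 2))
                    for k in nsclc_like_params()
                }
            )
            value = log_joint(params, cohort, rng.normal(size=(3, 2)), dag, include_prior=False)
            assert np.isfinite(value)

    def test_empty_cohort_rejected(self, dag):
        with pytest.raises(SCMError, match="empty"):
            log_joint(ParamSet({}), _three_patient_fixture().iloc[:0], np.zeros((0, 2)), dag)

    def test_fitness_sign_flip_preserves_likelihood_but_not_prior(self, dag, design):
        """Flipping U_f and every fitness-edge coefficient leaves the
        likelihood invariant; the nonnegativity constraint on the proxy
        loadings is what breaks this symmetry and anchors the latent."""
        params = nsclc_like_params()
        cohort, truth = generate_cohort(params, 5, seed=2)
        lat = truth.latents
        flipped_lat = lat * np.array([-1.0, 1.0])
        flipped = params.replace(
            alpha=-params["alpha"],
            ps_geq1_loading=-params["ps_geq1_loading"],
            egfr_lt60_loading=-params["egfr_lt60_loading"],
            treatment_fitness=-params["treatment_fitness"],
            outcome_fitness=-params["outcome_fitness"],
            interaction_fitness=-params["interaction_fitness"],
        )
        base = log_joint(params, cohort, lat, dag, include_prior=False)
        mirrored = log_joint(flipped, cohort, flipped_lat, dag, include_prior=False)
        assert mirrored == pytest.approx(base, rel=1e-10)
        assert log_prior(flipped, design) == -np.inf
        assert np.isfinite(log_prior(params, design))
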