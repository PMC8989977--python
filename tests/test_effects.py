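"""Effect estimation identities on degenerate (point-mass) posteriors and
consistency with the latent-posterior quadrature."""

import numpy as np
import pytest
from scipy import stats

from protect import effects as eff
from protect.inference import posterior_fitness
from protect.simulate import generate_cohort


@pytest.fixture(scope="module")
def cohort(default_params):
    c, _ = generate_cohort(default_params, 120, seed=31)
    return c


class TestIte:
    def test_homogeneous_effect_gives_constant_hr(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(cohort, {"outcome_treatment": -0.4, "weibull_shape": 1.0})
        mat = eff.ite_matrix(draws, cohort)
        np.testing.assert_allclose(np.exp(mat), np.exp(-0.4))
        res = eff.ate(draws, cohort)
        assert res.hr == pytest.approx(np.exp(-0.4), rel=1e-10)
        assert res.ci_low == pytest.approx(res.ci_high)  # zero-width interval

    def test_weight_loss_interaction_shifts_by_exactly_gamma(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(
            cohort,
            {"outcome_treatment": -0.4, "interaction_weight_loss": 0.3, "weibull_shape": 1.0},
        )
        mat = eff.ite_matrix(draws, cohort)
        wl = cohort["weight_loss"].to_numpy() == 1
        np.testing.assert_allclose(mat[:, wl], -0.1, atol=1e-12)
        np.testing.assert_allclose(mat[:, ~wl], -0.4, atol=1e-12)

    def test_received_treatment_is_ignored(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(cohort, {"outcome_treatment": -0.2, "weibull_shape": 1.0})
        flipped = cohort.assign(treatment=1 - cohort["treatment"])
        np.testing.assert_allclose(
            eff.ite_matrix(draws, cohort), eff.ite_matrix(draws, flipped)
        )

    def test_proxy_difference_equals_gamma_f_times_latent_shift(
        self, cohort, make_degenerate_draws, default_params
    ):
        """Two patients identical except for performance status differ in
        ITE by gamma_f times the shift in E[U_f | x] (quadrature oracle)."""
        values = dict(default_params.as_dict())
        values["interaction_fitness"] = -0.3
        draws = make_degenerate_draws(cohort, values)
        base = cohort.iloc[:1].assign(ps_geq1=0.0)
        frail = cohort.iloc[:1].assign(ps_geq1=1.0)
        d_ite = eff.ite(draws, frail)[0] - eff.ite(draws, base)[0]
        d_euf = posterior_fitness(draws, frail)[0, 0] - posterior_fitness(draws, base)[0, 0]
        assert d_ite == pytest.approx(-0.3 * d_euf, rel=1e-10)


class TestProbBenefit:
    def test_all_negative_draws(self):
        assert eff.prob_benefit(np.full(50, -0.1)) == 1.0

    def test_symmetric_draws(self):
        draws = np.concatenate([np.linspace(-1, -0.01, 50), np.linspace(0.01, 1, 50)])
        assert eff.prob_benefit(draws) == pytest.approx(0.5)

    def test_matches_normal_cdf(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(-0.2, 0.1, 200000)
        assert eff.prob_benefit(draws) == pytest.approx(stats.norm.cdf(2.0), abs=0.005)

    def test_empty_rejected(self):
        with pytest.raises(eff.EffectsError):
            eff.prob_benefit(np.array([]))


class TestAte:
    def test_full_cohort_weights_match_unweighted(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(
            cohort, {"outcome_treatment": -0.1, "interaction_stage_iiib_c": 0.2, "weibull_shape": 1.0}
        )
        plain = eff.ate(draws, cohort)
        weighted = eff.ate(draws, cohort, weights=np.ones(len(cohort)))
        np.testing.assert_allclose(plain.loghr_draws, weighted.loghr_draws)

    def test_empty_cohort_rejected(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(cohort, {"weibull_shape": 1.0})
        with pytest.raises(eff.EffectsError):
            eff.ate(draws, cohort.iloc[:0])


class TestPartialDependence:
    def test_pure_interaction_variable_recovers_gamma(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(
            cohort, {"interaction_weight_loss": 0.3, "weibull_shape": 1.0}
        )
        res = eff.partial_dependence(draws, cohort, "weight_loss")
        assert res.delta_loghr == pytest.approx(0.3, abs=1e-12)

    def test_proxy_with_closed_latent_pathway_is_null(self, cohort, make_degenerate_draws, default_params):
        values = dict(default_params.as_dict())
        values["interaction_fitness"] = 0.0
        draws = make_degenerate_draws(cohort, values)
        res = eff.partial_dependence(draws, cohort, "ps_geq1")
        assert res.delta_loghr == pytest.approx(0.0, abs=1e-12)

    def test_proxy_acts_through_latent_posterior_shift(
        self, cohort, make_degenerate_draws, default_params
    ):
        """With gamma_f != 0 the proxy's partial dependence equals gamma_f
        times the average shift in E[U_f | x] (brute-force averaging)."""
        values = dict(default_params.as_dict())
        values["interaction_fitness"] = -0.3
        draws = make_degenerate_draws(cohort, values)
        res = eff.partial_dependence(draws, cohort, "ps_geq1")
        lo = cohort.assign(ps_geq1=0.0)
        hi = cohort.assign(ps_geq1=1.0)
        shift = (posterior_fitness(draws, hi) - posterior_fitness(draws, lo)).mean()
        assert res.delta_loghr == pytest.approx(-0.3 * shift, rel=1e-10)

    def test_age_uses_one_standard_deviation(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(
            cohort, {"interaction_age_z": 0.25, "weibull_shape": 1.0}
        )
        res = eff.partial_dependence(draws, cohort, "age_z")
        assert res.delta_loghr == pytest.approx(0.25 * cohort["age_z"].std(ddof=1), rel=1e-10)

    def test_histology_contrasts_against_adeno(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(
            cohort, {"interaction_hist_squamous": -0.2, "weibull_shape": 1.0}
        )
        res = eff.partial_dependence(draws, cohort, "squamous")
        assert res.delta_loghr == pytest.approx(-0.2, abs=1e-12)

    def test_unknown_variable_rejected(self, cohort, make_degenerate_draws):
        draws = make_degenerate_draws(cohort, {"weibull_shape": 1.0})
        with pytest.raises(eff.EffectsError, match="unknown"):
            eff.partial_dependence(draws, cohort, "shoe_size")


def test_summary_tables_are_consistent(fitted, small_cohort):
    cohort, _ = small_cohort
    summary = eff.summarize(fitted, cohort, pd_variables=("weight_loss",), thin=5)
    assert len(summary.patient_table) == len(cohort)
    assert ((summary.patient_table["prob_benefit"] >= 0) & (summary.patient_table["prob_benefit"] <= 1)).all()
    assert (summary.patient_table["hr_low"] <= summary.patient_table["hr"]).all()
    assert (summary.patient_table["hr"] <= summary.patient_table["hr_high"]).all()
    assert summary.ate.ci_low <= summary.ate.hr <= summary.ate.ci_high


def test_rmst_difference_sign_matches_hazard_ratio(cohort, make_degenerate_draws):
    """A hazard ratio below one must translate into a positive restricted
    mean survival gain under the same Weibull model."""
    draws = make_degenerate_draws(
        cohort, {"outcome_treatment": -0.4, "outcome_intercept": -0.5, "weibull_shape": 1.2}
    )
    gain = eff.rmst_difference(draws, cohort, horizon=5.0, thin=10)
    assert np.all(gain > 0)
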