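import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from protect._collapsed import CollapsedModel
from protect._design import compile_design
from protect.dag import build_nsclc_dag
from protect.inference import MCMCConfig, PosteriorDraws, fit
from protect.simulate import generate_cohort, nsclc_like_params

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dag():
    return build_nsclc_dag()


@pytest.fixture(scope="session")
def design(dag):
    return compile_design(dag)


@pytest.fixture(scope="session")
def default_params():
    return nsclc_like_params()


@pytest.fixture(scope="session")
def small_cohort(default_params):
    cohort, truth = generate_cohort(
        default_params, 400, seed=11, switch=(-0.5, 1.0)
    )
    return cohort, truth


@pytest.fixture(scope="session")
def fitted(dag, small_cohort):
    """One reduced-scale posterior fit shared by the effect, baseline and
    sensitivity tests."""
    cohort, _ = small_cohort
    cfg = MCMCConfig.reduced(
        seed=7, n_chains=2, n_warmup=400, n_samples=500, quad_fitness=5, quad_behavior=5
    )
    return fit(dag, cohort, mcmc=cfg)


@pytest.fixture()
def make_degenerate_draws(design):
    """Factory for a PosteriorDraws whose every draw equals one fixed
    parameter assignment — turns posterior functionals into exact
    arithmetic identities."""

    def factory(cohort, values: dict, n_draws: int = 25) -> PosteriorDraws:
        model = CollapsedModel(design, design.pack_data(cohort), quad_fitness=7, quad_behavior=7)
        theta = design.pack(values)
        theta[model.positive] = np.maximum(theta[model.positive], 1e-12)
        x = model.to_unconstrained(theta)
        raw = np.tile(x, (2, n_draws, 1))
        cfg = MCMCConfig.reduced(seed=0, n_chains=2, n_warmup=1, n_samples=n_draws)
        return PosteriorDraws(
            model=model,
            config=cfg,
            raw=raw,
            logposts=np.zeros((2, n_draws)),
            divergences=np.zeros(2, dtype=int),
            n_leapfrogs=0,
        )

    return factory
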