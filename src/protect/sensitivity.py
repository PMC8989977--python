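"""Sensitivity analyses of the average treatment effect.

Three analyses probe the robustness of the ATE:

1. *Omitted confounder*: the model is re-estimated with an additional
   independent standard-normal latent entering the treatment logit and the
   log-hazard with fixed, user-chosen coefficients; the grid of
   (theta_treatment, theta_outcome) pairs maps how strong an unmodeled
   confounder would have to be to move the estimate.
2. *Weight-loss prevalence reweighting*: weight loss is analyzed
   complete-case (its missingness is plausibly related to its presence),
   so the true prevalence is unknown; the ATE is recomputed under
   hypothetical prevalences by reweighting patients.
3. *RCT-like restriction*: the cohort is restricted to patients whose
   model-predicted probability of concurrent treatment exceeds a cutoff
   (0/25/50/75%), emulating the selection into trials of patients deemed
   fit enough for intensive treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._design import compile_design
from .dag import DAGSpec
from .effects import AteResult, ate, ite_matrix
from .inference import MCMCConfig, PosteriorDraws, _run_chains
from ._collapsed import CollapsedModel
from .params import PriorSpec


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityGridResult:
    table: pd.DataFrame  # theta_treatment, theta_outcome, hr, ci_low, ci_high
    reference: AteResult | None = None


def omitted_confounder(
    dag: DAGSpec,
    cohort: pd.DataFrame,
    grid: list[tuple[float, float]],
    mcmc: MCMCConfig,
    priors: PriorSpec | None = None,
    reference: AteResult | None = None,
) -> SensitivityGridResult:
    """Refit the model per grid point with an extra independent N(0, 1)
    confounder at fixed coefficients (theta_treatment on the treatment
    logit, theta_outcome on the log-hazard); all other parameters are
    re-estimated.  At the origin (0, 0) the augmentation is null and the
    ATE reproduces the base fit up to Monte-Carlo error."""
    rows = []
    for theta_t, theta_o in grid:
        design = compile_design(dag, extra_confounder=(float(theta_t), float(theta_o)))
        model = CollapsedModel(
            design,
            design.pack_data(cohort),
            priors=priors,
            quad_fitness=mcmc.quad_fitness,
            quad_behavior=mcmc.quad_behavior,
        )
        draws = _run_chains(model, mcmc)
        res = ate(draws, cohort)
        rows.append(
            {
                "theta_treatment": theta_t,
                "theta_outcome": theta_o,
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "loghr": res.loghr_mean,
            }
        )
    return SensitivityGridResult(table=pd.DataFrame(rows), reference=reference)


def weightloss_reweight(
    draws: PosteriorDraws,
    cohort: pd.DataFrame,
    hypothetical_prevalence: float,
    ites: np.ndarray | None = None,
) -> AteResult:
    """ATE under a hypothetical weight-loss prevalence pi: patients with
    weight loss get weight pi / p-hat and the others (1 - pi) / (1 - p-hat),
    where p-hat is the observed complete-case prevalence; the ATE is the
    weighted mean of the ITE draws."""
    pi = float(hypothetical_prevalence)
    wl = cohort["weight_loss"].to_numpy(float) > 0.5
    p_hat = wl.mean()
    if pi in (0.0, 1.0):
        stratum = ~wl if pi == 0.0 else wl
        if stratum.sum() == 0:
            raise SensitivityError(
                f"prevalence {pi} requires a non-empty corresponding stratum"
            )
    if not (0.0 <= pi <= 1.0):
        raise SensitivityError("prevalence must lie in [0, 1]")
    w = np.where(wl, pi / p_hat if p_hat > 0 else 0.0, (1 - pi) / (1 - p_hat) if p_hat < 1 else 0.0)
    return ate(draws, cohort, weights=w, ites=ites)


def rct_restriction(
    draws: PosteriorDraws,
    cohort: pd.DataFrame,
    cutoffs: tuple[float, ...] = (0.0, 0.25, 0.50, 0.75),
) -> pd.DataFrame:
    """ATE restricted to patients with model-predicted probability of
    concurrent treatment above each cutoff.

    The predicted propensity marginalizes latent fitness over its posterior
    given the pre-treatment proxies (a new patient's latent is unknown),
    averaged across posterior draws.  Subsets are nested by construction;
    an empty subset is reported with n = 0 rather than raised.
    """
    data = draws.design.pack_data(cohort)
    theta = draws.theta_matrix(thin=max(1, draws.n_draws_total // 400))
    ps = np.zeros(data.n)
    for s in range(len(theta)):
        ps += draws.model.propensity(theta[s], data)
    ps /= len(theta)
    ites = ite_matrix(draws, cohort)
    rows = []
    for cutoff in cutoffs:
        mask = ps > cutoff
        if mask.sum() == 0:
            rows.append(
                {"cutoff": cutoff, "n": 0, "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan}
            )
            continue
        sub = ites[:, mask]
        loghr = sub.mean(1)
        lo, hi = np.percentile(loghr, [2.5, 97.5])
        rows.append(
            {
                "cutoff": cutoff,
                "n": int(mask.sum()),
                "hr": float(np.exp(loghr.mean())),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
            }
        )
    return pd.DataFrame(rows)
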