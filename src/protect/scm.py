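"""The generative model: structural equations and the joint log-density.

Every structural equation is linear on its link scale: Gaussian latents
(unit scale, fitness mean linear in standardized age), logit links for the
binary/categorical proxies and the treatment decision, and a Weibull
proportional-hazards model for right-censored overall survival.  The
treatment-covariate interaction terms in the survival equation (including a
treatment x latent-fitness term) are what make the individual treatment
effect heterogeneous.

This module is the plain, per-patient reference implementation that the
fast collapsed likelihood in :mod:`protect._collapsed` is tested against.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._design import CohortData, ModelDesign, compile_design
from ._numutil import (
    bernoulli_loglik,
    halfnormal_logpdf,
    normal_logpdf,
    sigmoid,
    softplus,
)
from .dag import DAGSpec, HISTOLOGY_DUMMIES, HISTOLOGY_LEVELS, build_nsclc_dag
from .params import ParamSet, PriorSpec


class SCMError(ValueError):
    pass


def _parent_value(parent_values: Mapping[str, float], node: str, parent: str) -> float:
    if parent not in parent_values:
        raise SCMError(f"node {node!r} is missing a value for parent {parent!r}")
    return float(parent_values[parent])


def _histology_dummy_values(parent_values: Mapping[str, float], node: str) -> dict[str, float]:
    """Accept either a 'histology' level label or explicit dummy values."""
    if "histology" in parent_values and isinstance(parent_values["histology"], str):
        level = parent_values["histology"]
        if level not in HISTOLOGY_LEVELS:
            raise SCMError(f"unknown histology level {level!r}")
        return {
            "hist_squamous": float(level == "squamous"),
            "hist_other": float(level == "other"),
        }
    return {d: _parent_value(parent_values, node, d) for d in HISTOLOGY_DUMMIES}


def linear_predictor(
    params: ParamSet,
    node: str,
    parent_values: Mapping[str, float],
    design: ModelDesign | None = None,
):
    """Link-scale linear predictor of ``node`` given its parents' values.

    Latent parents are keyed ``"fitness"`` / ``"behavior"``; histology may
    be given as a level label or as the two dummies.  For the categorical
    histology node an array of non-reference-level logits is returned.
    """
    design = design or _default_design()
    get = lambda name: params.get(name, 0.0)

    for bn in design.binary_nodes:
        if bn.name == node:
            lp = get(f"{node}_intercept")
            if bn.latent is not None:
                u = _parent_value(parent_values, node, bn.latent)
                lp += bn.sign * get(f"{node}_loading") * u
            return lp

    if design.categorical is not None and node == design.categorical:
        u = (
            _parent_value(parent_values, node, "behavior")
            if design.categorical_latent
            else 0.0
        )
        return np.array(
            [
                get(f"histology_{lv}_intercept") + get(f"histology_{lv}_loading") * u
                for lv in HISTOLOGY_LEVELS[1:]
            ]
        )

    if node == design.dag.treatment:
        lp = get("treatment_intercept")
        if design.treat_on_fitness:
            lp += get("treatment_fitness") * _parent_value(parent_values, node, "fitness")
        values = dict(parent_values)
        if design.categorical in design.dag.parents(node):
            values.update(_histology_dummy_values(parent_values, node))
        for c in design.treatment_covs:
            lp += get(f"treatment_{c}") * _parent_value(values, node, c)
        return lp

    if node == design.dag.outcome:
        values = dict(parent_values)
        if design.categorical in design.dag.parents(node):
            values.update(_histology_dummy_values(parent_values, node))
        a = _parent_value(values, node, "treatment")
        lp = get("outcome_intercept") + get("outcome_treatment") * a
        if design.out_on_fitness:
            lp += get("outcome_fitness") * _parent_value(values, node, "fitness")
        if design.out_on_behavior:
            lp += get("outcome_behavior") * _parent_value(values, node, "behavior")
        for c in design.outcome_covs:
            lp += get(f"outcome_{c}") * _parent_value(values, node, c)
        inter = 0.0
        for c in design.interaction_covs:
            inter += get(f"interaction_{c}") * _parent_value(values, node, c)
        if design.interaction_fitness:
            inter += get("interaction_fitness") * _parent_value(values, node, "fitness")
        return lp + a * inter

    if node == design.dag.latent_fitness:
        if design.fitness_cause is None:
            return 0.0
        return get("alpha") * _parent_value(parent_values, node, design.fitness_cause)

    if node == design.dag.latent_behavior:
        return 0.0

    raise SCMError(f"no structural equation for node {node!r}")


def survival_logdensity(params: ParamSet, eta: float, time, event) -> float:
    """Weibull proportional-hazards log-density contribution.

    ``event * (log k + (k-1) log t + eta) - t^k exp(eta)``; reduces to the
    exponential log-likelihood at shape ``k = 1``.
    """
    time = np.asarray(time, float)
    if np.any(time <= 0):
        raise SCMError("survival time must be positive")
    k = params.shape
    event = np.asarray(event, float)
    log_t = np.log(time)
    out = event * (np.log(k) + (k - 1.0) * log_t + eta) - time**k * np.exp(eta)
    return float(out) if out.ndim == 0 else out


def log_prior(params: ParamSet, design: ModelDesign, priors: PriorSpec | None = None) -> float:
    priors = priors or PriorSpec()
    total = 0.0
    for name, positive in design.param_layout:
        value = params.get(name, 1.0 if name == "weibull_shape" else 0.0)
        if name == "weibull_shape":
            total += float(halfnormal_logpdf(value, priors.scale_shape))
        elif positive:
            total += float(halfnormal_logpdf(value, priors.scale_loading))
        else:
            total += float(normal_logpdf(value, 0.0, priors.scale_coef))
    return total


def log_joint(
    params: ParamSet,
    cohort: pd.DataFrame,
    latents: np.ndarray,
    dag: DAGSpec | None = None,
    priors: PriorSpec | None = None,
    include_prior: bool = True,
) -> float:
    """Joint log-density of a cohort, its latents and the parameters.

    ``latents`` is an (n, 2) array of per-patient (U_f, U_b).  The sum runs
    over the standard-normal density of U_b, the Normal(alpha * age_z, 1)
    density of U_f, the logit log-masses of proxies and treatment, and the
    Weibull survival contribution; the parameter log-prior is added unless
    ``include_prior=False``.
    """
    dag = dag or build_nsclc_dag()
    design = compile_design(dag)
    if len(cohort) == 0:
        raise SCMError("cohort is empty")
    latents = np.atleast_2d(np.asarray(latents, float))
    if latents.shape != (len(cohort), 2):
        raise SCMError(f"latents must have shape ({len(cohort)}, 2)")

    total = 0.0
    for i, row in enumerate(cohort.to_dict("records")):
        u_f, u_b = latents[i]
        values = {**row, "fitness": u_f, "behavior": u_b}
        if design.has_behavior:
            total += float(normal_logpdf(u_b, 0.0, 1.0))
        if design.has_fitness:
            mean = linear_predictor(params, dag.latent_fitness, values, design)
            total += float(normal_logpdf(u_f, mean, 1.0))
        for bn in design.binary_nodes:
            logit = linear_predictor(params, bn.name, values, design)
            total += float(bernoulli_loglik(float(row[bn.name]), logit))
        if design.categorical is not None:
            logits = linear_predictor(params, design.categorical, values, design)
            full = np.concatenate([[0.0], logits])
            level = HISTOLOGY_LEVELS.index(str(row[design.categorical]))
            total += float(full[level] - np.log(np.sum(np.exp(full - full.max()))) - full.max())
        logit_a = linear_predictor(params, dag.treatment, values, design)
        total += float(bernoulli_loglik(float(row["treatment"]), logit_a))
        eta = linear_predictor(params, dag.outcome, values, design)
        total += survival_logdensity(params, eta, float(row["time"]), float(row["event"]))

    if include_prior:
        total += log_prior(params, design, priors)
    return total


_DEFAULT_DESIGN: ModelDesign | None = None


def _default_design() -> ModelDesign:
    global _DEFAULT_DESIGN
    if _DEFAULT_DESIGN is None:
        _DEFAULT_DESIGN = compile_design(build_nsclc_dag())
    return _DEFAULT_DESIGN
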