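"""Forward simulation of cohorts from the structural causal model.

The generator ancestrally samples the behavior-fitness graph with known
ground truth, so parameter recovery, model selection, effect estimation and
the sensitivity analyses can all be validated without access to patient
data.  The default ``nsclc_like`` scenario targets the printed margins of a
real stage III NSCLC cohort (n = 504; concurrent treatment 224/504; ECOG
performance status >= 1 about 45%; substage IIIB/C about 46%; weight loss
about 45%; eGFR < 60 about 10%; histology adeno/squamous/other roughly
41/40/19%; about 70% deaths observed) by numerically back-solving the
structural-equation intercepts; these are calibration targets for realism,
not quantities the package claims to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from ._numutil import gauss_hermite, sigmoid
from .dag import HISTOLOGY_LEVELS
from .params import ParamSet


class SimulationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Ground truth recorded during simulation: the generating parameters,
    the per-patient latents, and the true individual/average treatment
    effects on the log-hazard-ratio scale."""

    params: ParamSet
    latents: np.ndarray  # (n, 2): columns U_f, U_b
    true_ite_loghr: np.ndarray
    true_ate_loghr: float


# margins used when back-solving intercepts (calibration targets)
_MARGINS = {
    "ps_geq1": 0.455,
    "egfr_lt60": 0.10,
    "weight_loss": 0.45,
    "stage_iiib_c": 0.46,
    "hist_squamous": 0.40,
    "hist_other": 0.19,
    "treatment": 0.444,
    "event": 0.70,
}

# reference slopes of the nsclc-like scenario
_BASE_SLOPES = {
    "alpha": -0.35,
    "ps_geq1_loading": 1.2,
    "egfr_lt60_loading": 1.0,
    "weight_loss_loading": 1.0,
    "stage_iiib_c_loading": 0.8,
    "histology_squamous_loading": 0.6,
    "histology_other_loading": 0.2,
    "treatment_fitness": 1.0,
    "treatment_age_z": -0.2,
    "treatment_stage_iiib_c": -0.4,
    "treatment_weight_loss": -0.1,
    "treatment_hist_squamous": -0.4,
    "treatment_hist_other": 0.0,
    "outcome_treatment": 0.0,
    "outcome_fitness": -0.6,
    "outcome_behavior": 0.35,
    "outcome_age_z": 0.10,
    "outcome_stage_iiib_c": 0.25,
    "outcome_weight_loss": 0.15,
    "outcome_hist_squamous": 0.05,
    "outcome_hist_other": 0.10,
    "interaction_age_z": 0.0,
    "interaction_stage_iiib_c": 0.15,
    "interaction_weight_loss": 0.15,
    "interaction_hist_squamous": -0.10,
    "interaction_hist_other": 0.05,
    "interaction_fitness": -0.15,
    "weibull_shape": 1.1,
}

DEFAULT_CENSORING = (0.5, 8.0)


@lru_cache(maxsize=32)
def _calibrated(slope_items: tuple, censoring: tuple) -> dict[str, float]:
    slopes = dict(_BASE_SLOPES)
    slopes.update(dict(slope_items))
    z, w = gauss_hermite(31)

    values = dict(slopes)

    # marginal scale of U_f = alpha * age + eps, age ~ N(0,1)
    s_f = float(np.hypot(1.0, slopes["alpha"]))

    def solve_logit(target: float, loading: float, scale: float) -> float:
        fn = lambda a: float(w @ sigmoid(a + loading * scale * z)) - target
        return brentq(fn, -15.0, 15.0)

    # adverse-coded fitness proxies: logit = a - b * U_f
    values["ps_geq1_intercept"] = solve_logit(
        _MARGINS["ps_geq1"], -slopes["ps_geq1_loading"], s_f
    )
    values["egfr_lt60_intercept"] = solve_logit(
        _MARGINS["egfr_lt60"], -slopes["egfr_lt60_loading"], s_f
    )
    values["weight_loss_intercept"] = solve_logit(
        _MARGINS["weight_loss"], slopes["weight_loss_loading"], 1.0
    )
    values["stage_iiib_c_intercept"] = solve_logit(
        _MARGINS["stage_iiib_c"], slopes["stage_iiib_c_loading"], 1.0
    )

    def hist_margins(a: np.ndarray) -> np.ndarray:
        l1 = a[0] + slopes["histology_squamous_loading"] * z
        l2 = a[1] + slopes["histology_other_loading"] * z
        mx = np.maximum(0.0, np.maximum(l1, l2))
        denom = np.exp(-mx) + np.exp(l1 - mx) + np.exp(l2 - mx)
        return np.array(
            [w @ (np.exp(l1 - mx) / denom), w @ (np.exp(l2 - mx) / denom)]
        )

    target = np.array([_MARGINS["hist_squamous"], _MARGINS["hist_other"]])
    sol = root(lambda a: hist_margins(a) - target, x0=np.zeros(2))
    values["histology_squamous_intercept"] = float(sol.x[0])
    values["histology_other_intercept"] = float(sol.x[1])

    # joint margins for treatment and event fraction by fixed-seed Monte Carlo
    rng = np.random.default_rng(20220407)
    n = 120_000
    age = rng.standard_normal(n)
    uf = values["alpha"] * age + rng.standard_normal(n)
    ub = rng.standard_normal(n)
    stage = (
        rng.random(n)
        < sigmoid(values["stage_iiib_c_intercept"] + values["stage_iiib_c_loading"] * ub)
    ).astype(float)
    wl = (
        rng.random(n)
        < sigmoid(values["weight_loss_intercept"] + values["weight_loss_loading"] * ub)
    ).astype(float)
    l1 = values["histology_squamous_intercept"] + values["histology_squamous_loading"] * ub
    l2 = values["histology_other_intercept"] + values["histology_other_loading"] * ub
    logits = np.column_stack([np.zeros(n), l1, l2])
    p = np.exp(logits - logits.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    u = rng.random(n)
    hist = (u[:, None] > p.cumsum(1)).sum(1)
    h_sq, h_ot = (hist == 1).astype(float), (hist == 2).astype(float)

    x_treat = (
        values["treatment_fitness"] * uf
        + values["treatment_age_z"] * age
        + values["treatment_stage_iiib_c"] * stage
        + values["treatment_weight_loss"] * wl
        + values["treatment_hist_squamous"] * h_sq
        + values["treatment_hist_other"] * h_ot
    )
    values["treatment_intercept"] = brentq(
        lambda t0: float(np.mean(sigmoid(t0 + x_treat))) - _MARGINS["treatment"],
        -15.0,
        15.0,
    )
    a_sim = (rng.random(n) < sigmoid(values["treatment_intercept"] + x_treat)).astype(float)

    eta_no_int = (
        values["outcome_treatment"] * a_sim
        + values["outcome_fitness"] * uf
        + values["outcome_behavior"] * ub
        + values["outcome_age_z"] * age
        + values["outcome_stage_iiib_c"] * stage
        + values["outcome_weight_loss"] * wl
        + values["outcome_hist_squamous"] * h_sq
        + values["outcome_hist_other"] * h_ot
        + a_sim
        * (
            values["interaction_age_z"] * age
            + values["interaction_stage_iiib_c"] * stage
            + values["interaction_weight_loss"] * wl
            + values["interaction_hist_squamous"] * h_sq
            + values["interaction_hist_other"] * h_ot
            + values["interaction_fitness"] * uf
        )
    )
    k = values["weibull_shape"]
    c = rng.uniform(censoring[0], censoring[1], n)

    def event_frac(b0: float) -> float:
        return float(np.mean(1.0 - np.exp(-(c**k) * np.exp(b0 + eta_no_int))))

    values["outcome_intercept"] = brentq(
        lambda b0: event_frac(b0) - _MARGINS["event"], -12.0, 6.0
    )
    return values


def nsclc_like_params(censoring: tuple[float, float] = DEFAULT_CENSORING, **overrides) -> ParamSet:
    """Reference generating parameters for the nsclc-like scenario.

    Slope overrides (e.g. ``treatment_fitness=1.2``) are applied before the
    intercepts are back-solved, so the cohort margins are preserved across
    scenarios.
    """
    unknown = set(overrides) - set(_BASE_SLOPES)
    if unknown:
        raise SimulationError(f"unknown parameter overrides: {sorted(unknown)}")
    values = _calibrated(tuple(sorted(overrides.items())), tuple(censoring))
    return ParamSet(values)


def generate_cohort(
    params: ParamSet,
    n: int,
    censoring: tuple[float, float] = DEFAULT_CENSORING,
    seed: int = 0,
    switch: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Ancestral sampling of a coded cohort with recorded ground truth.

    Survival times are drawn from the Weibull proportional-hazards model by
    inverse-CDF sampling; censoring is administrative-uniform on
    ``censoring = (c_min, c_max)`` and independent of everything else.
    ``switch``, when given as ``(intercept, slope)``, simulates a negative
    treatment switch as a Bernoulli draw with logit
    ``intercept + slope * (-U_f)`` (frailer patients switch more often).
    """
    if n < 1:
        raise SimulationError("n must be >= 1")
    c_min, c_max = censoring
    if not (0 < c_min < c_max):
        raise SimulationError(f"invalid censoring window {censoring}")
    rng = np.random.default_rng(seed)
    get = params.get

    age = rng.standard_normal(n)
    uf = get("alpha") * age + rng.standard_normal(n)
    ub = rng.standard_normal(n)

    def bern(logit):
        return (rng.random(n) < sigmoid(logit)).astype(float)

    ps = bern(get("ps_geq1_intercept") - get("ps_geq1_loading") * uf)
    egfr = bern(get("egfr_lt60_intercept") - get("egfr_lt60_loading") * uf)
    wl = bern(get("weight_loss_intercept") + get("weight_loss_loading") * ub)
    stage = bern(get("stage_iiib_c_intercept") + get("stage_iiib_c_loading") * ub)

    l1 = get("histology_squamous_intercept") + get("histology_squamous_loading") * ub
    l2 = get("histology_other_intercept") + get("histology_other_loading") * ub
    logits = np.column_stack([np.zeros(n), l1, l2])
    p = np.exp(logits - logits.max(1, keepdims=True))
    p /= p.sum(1, keepdims=True)
    hist_code = (rng.random(n)[:, None] > p.cumsum(1)).sum(1)
    h_sq, h_ot = (hist_code == 1).astype(float), (hist_code == 2).astype(float)

    logit_a = (
        get("treatment_intercept")
        + get("treatment_fitness") * uf
        + get("treatment_age_z") * age
        + get("treatment_stage_iiib_c") * stage
        + get("treatment_weight_loss") * wl
        + get("treatment_hist_squamous") * h_sq
        + get("treatment_hist_other") * h_ot
    )
    a = bern(logit_a)

    ite = (
        get("outcome_treatment")
        + get("interaction_age_z") * age
        + get("interaction_stage_iiib_c") * stage
        + get("interaction_weight_loss") * wl
        + get("interaction_hist_squamous") * h_sq
        + get("interaction_hist_other") * h_ot
        + get("interaction_fitness") * uf
    )
    eta = (
        get("outcome_intercept")
        + get("outcome_fitness") * uf
        + get("outcome_behavior") * ub
        + get("outcome_age_z") * age
        + get("outcome_stage_iiib_c") * stage
        + get("outcome_weight_loss") * wl
        + get("outcome_hist_squamous") * h_sq
        + get("outcome_hist_other") * h_ot
        + a * ite
    )
    k = params.shape
    t_event = (rng.exponential(1.0, n) * np.exp(-eta)) ** (1.0 / k)
    t_cens = rng.uniform(c_min, c_max, n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-8)
    event = (t_event <= t_cens).astype(int)

    cohort = pd.DataFrame(
        {
            "age_z": age,
            "ps_geq1": ps,
            "egfr_lt60": egfr,
            "weight_loss": wl,
            "histology": np.asarray(HISTOLOGY_LEVELS)[hist_code],
            "stage_iiib_c": stage,
            "treatment": a.astype(int),
            "time": time,
            "event": event,
        }
    )
    if switch is not None:
        s0, s1 = switch
        cohort["switch"] = bern(s0 + s1 * (-uf)).astype(int)

    truth = SimTruth(
        params=params,
        latents=np.column_stack([uf, ub]),
        true_ite_loghr=ite,
        true_ate_loghr=float(ite.mean()),
    )
    return cohort, truth


def true_effects(truth: SimTruth, cohort: pd.DataFrame) -> tuple[float, np.ndarray]:
    """Recompute the true effects from the recorded parameters and latents
    (the generator's own ITE definition: the treatment coefficient plus the
    interaction terms evaluated at the patient's covariates and true U_f)."""
    if len(cohort) != len(truth.latents):
        raise SimulationError("truth does not match cohort")
    get = truth.params.get
    h_sq = (cohort["histology"] == "squamous").to_numpy(float)
    h_ot = (cohort["histology"] == "other").to_numpy(float)
    ite = (
        get("outcome_treatment")
        + get("interaction_age_z") * cohort["age_z"].to_numpy()
        + get("interaction_stage_iiib_c") * cohort["stage_iiib_c"].to_numpy()
        + get("interaction_weight_loss") * cohort["weight_loss"].to_numpy()
        + get("interaction_hist_squamous") * h_sq
        + get("interaction_hist_other") * h_ot
        + get("interaction_fitness") * truth.latents[:, 0]
    )
    return float(ite.mean()), ite


def inject_missingness(
    cohort: pd.DataFrame,
    mechanism: str,
    rate: float | None = None,
    p_miss_given_absent: float | None = None,
    p_miss_given_present: float | None = None,
    field: str = "weight_loss",
    seed: int = 0,
) -> pd.DataFrame:
    """Blank entries of ``field``.

    ``mcar`` blanks uniformly at random at ``rate``.  ``mnar_weightloss``
    emulates differential recording of weight loss in charts: the value goes
    missing with probability ``p_miss_given_absent`` when weight loss is
    absent and ``p_miss_given_present`` when present (the latter must not
    exceed the former: pronounced weight loss is the better-recorded state).
    """
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    if mechanism == "mcar":
        if rate is None or not (0 <= rate <= 1):
            raise SimulationError("mcar requires rate in [0, 1]")
        mask = rng.random(len(out)) < rate
    elif mechanism == "mnar_weightloss":
        if p_miss_given_absent is None or p_miss_given_present is None:
            raise SimulationError("mnar_weightloss requires both recording probabilities")
        if p_miss_given_present > p_miss_given_absent:
            raise SimulationError(
                "p_miss_given_present must not exceed p_miss_given_absent"
            )
        present = out[field].to_numpy(float) > 0.5
        p = np.where(present, p_miss_given_present, p_miss_given_absent)
        mask = rng.random(len(out)) < p
    else:
        raise SimulationError(f"unknown missingness mechanism {mechanism!r}")
    out.loc[mask, field] = np.nan
    return out
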