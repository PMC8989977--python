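"""Conventional-adjustment comparators and model-fit metrics.

These are the estimators the structural model is contrasted with: the
unadjusted and multivariable Cox proportional-hazards models, the inverse
propensity weighted Cox model (all of which can only adjust for *observed*
covariates and therefore remain exposed to the unobserved-fitness
confounding), Harrell's concordance index, the Mann-Whitney AUC, and the
treatment-switch model check (patients with lower reconstructed fitness
should discontinue or de-intensify treatment more often).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index
from sklearn.metrics import roc_auc_score

from .inference import PosteriorDraws, posterior_fitness
from .params import add_histology_dummies


class BaselinesError(ValueError):
    pass


@dataclass
class HazardRatioEstimate:
    hr: float
    ci_low: float
    ci_high: float
    n: int
    label: str
    interval_type: str = "confidence"
    coefficients: pd.Series | None = field(default=None, repr=False)


def _expand_covariates(cohort: pd.DataFrame, covariates: list[str]) -> tuple[pd.DataFrame, list[str]]:
    df = add_histology_dummies(cohort)
    cols: list[str] = []
    for c in covariates:
        cols.extend(["hist_squamous", "hist_other"] if c == "histology" else [c])
    kept = []
    for c in cols:
        if df[c].nunique() <= 1:
            warnings.warn(f"dropping zero-variance covariate {c!r}", stacklevel=3)
        else:
            kept.append(c)
    return df, kept


def cox_fit(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    weights: np.ndarray | None = None,
    robust: bool = False,
) -> HazardRatioEstimate:
    """Multivariable Cox proportional-hazards fit (Efron tie handling,
    Newton iterations, Wald 95% interval) for the treatment hazard ratio.

    An empty covariate list gives the unadjusted estimate.  Zero-variance
    covariates are dropped with a warning.
    """
    covariates = covariates or []
    if cohort["event"].sum() < 1:
        raise BaselinesError("no events in cohort")
    df, cols = _expand_covariates(cohort, covariates)
    model_cols = ["treatment"] + cols + ["time", "event"]
    frame = df[model_cols].astype(float)
    if weights is not None:
        frame = frame.assign(_w=np.asarray(weights, float))
    cph = CoxPHFitter()
    cph.fit(
        frame,
        duration_col="time",
        event_col="event",
        weights_col="_w" if weights is not None else None,
        robust=robust or weights is not None,
        fit_options={"precision": 1e-10, "r_precision": 1e-14, "step_size": 1.0},
    )
    row = cph.summary.loc["treatment"]
    label = "adjusted Cox" if cols else "unadjusted Cox"
    return HazardRatioEstimate(
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        n=len(cohort),
        label=label if weights is None else "IPW Cox",
        coefficients=cph.params_.copy(),
    )


def estimate_propensity(
    cohort: pd.DataFrame, covariates: list[str]
) -> np.ndarray:
    """Logistic propensity of concurrent treatment on observed covariates
    (maximum likelihood; intercept-only when the list is empty)."""
    df, cols = _expand_covariates(cohort, covariates)
    X = sm.add_constant(df[cols].astype(float), has_constant="add")
    fit = sm.Logit(df["treatment"].astype(float), X).fit(disp=False)
    return np.asarray(fit.predict(X), float)


def ipw_cox(cohort: pd.DataFrame, propensity_covariates: list[str]) -> HazardRatioEstimate:
    """Inverse propensity weighted Cox model with stabilized weights
    P(A)/P(A|x) for the treated and (1-P(A))/(1-P(A|x)) for the controls,
    and a robust sandwich variance."""
    ps = estimate_propensity(cohort, propensity_covariates)
    if np.any(ps < 1e-6) or np.any(ps > 1 - 1e-6):
        raise BaselinesError(
            "estimated propensities within 1e-6 of 0 or 1; trim the cohort "
            "or reduce the propensity model"
        )
    a = cohort["treatment"].to_numpy(float)
    marginal = a.mean()
    w = np.where(a == 1, marginal / ps, (1 - marginal) / (1 - ps))
    est = cox_fit(cohort, covariates=[], weights=w, robust=True)
    est.label = "IPW Cox"
    est.coefficients = None
    return est


def harrell_c(scores, times, events) -> float:
    """Harrell's concordance index of a risk score against right-censored
    survival: the fraction of comparable pairs in which the patient with
    the higher risk score fails earlier (score ties count 1/2)."""
    scores = np.asarray(scores, float)
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    if not (len(scores) == len(times) == len(events)):
        raise BaselinesError("scores, times and events must have equal length")
    try:
        # lifelines counts concordance of *survival-directed* predictions
        return float(concordance_index(times, -scores, events))
    except ZeroDivisionError as err:
        raise BaselinesError("no comparable pairs") from err


def auc(scores, labels) -> float:
    """Mann-Whitney rank AUC with tie correction."""
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise BaselinesError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def switch_check(
    draws: PosteriorDraws, cohort: pd.DataFrame, arm: int = 1
) -> float:
    """AUC of *negative* reconstructed fitness (posterior mean E[U_f | x]
    from pre-treatment variables) for predicting a negative treatment
    switch within one treatment arm."""
    if "switch" not in cohort.columns:
        raise BaselinesError("cohort has no switch column")
    sub = cohort[cohort["treatment"] == arm]
    if len(sub) == 0 or sub["switch"].sum() == 0:
        raise BaselinesError(f"no switches observed in arm {arm}")
    fitness = posterior_fitness(draws, sub, include_treatment=False).mean(0)
    return auc(-fitness, sub["switch"].to_numpy(float))


def comparison_table(estimates: list[HazardRatioEstimate]) -> pd.DataFrame:
    """Side-by-side estimator table (the multi-method overview figure as a
    tidy frame)."""
    return pd.DataFrame(
        [
            {
                "estimator": e.label,
                "hr": e.hr,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "interval": e.interval_type,
                "n": e.n,
            }
            for e in estimates
        ]
    )
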