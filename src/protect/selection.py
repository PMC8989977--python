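"""Model selection: reject candidates that fail to reproduce the
fitness-induced correlations, then pool survivors by Bayesian model
averaging.

The latent fitness induces correlations between its effect variables (the
fitness proxies, the treatment decision and the outcome).  A candidate
model is therefore asked to predict each of these targets for held-out
patients — integrating the latent over its posterior given the patient's
*other* observed variables — and is compared with a baseline regression of
the target on only its direct observed causes (fitness removed; for a
proxy whose sole parent is fitness the baseline collapses to an
intercept-only model).  A candidate that cannot beat the baseline on any
target by more than one fold-level standard error has failed to pick up
the confounding structure and is rejected.  Accepted candidates receive
pseudo-BMA weights proportional to the exponentiated total held-out log
predictive density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from ._collapsed import CollapsedModel, map_estimate
from ._design import compile_design
from ._numutil import sigmoid
from .dag import DAGSpec, HISTOLOGY_LEVELS
from .inference import MCMCConfig, _run_chains
from .params import PriorSpec

# candidate-vs-baseline score differences smaller than this are numerical
# ties (identical model classes refit by the same optimizer), never evidence
TIE_TOLERANCE = 1e-3


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class CandidateModel:
    dag: DAGSpec
    label: str
    priors: PriorSpec = field(default_factory=PriorSpec)
    quad: int = 7


@dataclass
class CVScore:
    score: float
    fold_scores: np.ndarray
    kind: str  # "lpd" (mean held-out log predictive density) or "concordance"


@dataclass
class SelectionReport:
    table: pd.DataFrame  # candidate x target rows
    accepted: list[str]
    weights: dict[str, float]


def allowed_targets(dag: DAGSpec) -> list[str]:
    """Effect variables of latent fitness: its proxies, the treatment and
    the outcome."""
    return dag.names("proxy_of_fitness") + [dag.treatment, dag.outcome]


def _folds(n: int, K: int, seed: int):
    if K < 2:
        raise SelectionError("K must be >= 2")
    kf = KFold(n_splits=min(K, n), shuffle=True, random_state=seed)
    return list(kf.split(np.arange(n)))


def _fit_fold(candidate: CandidateModel, train: pd.DataFrame, method: str, seed: int):
    design = compile_design(candidate.dag)
    model = CollapsedModel(
        design,
        design.pack_data(train),
        priors=candidate.priors,
        quad_fitness=candidate.quad,
        quad_behavior=candidate.quad,
    )
    if method == "map":
        x = map_estimate(model, rng=np.random.default_rng(seed))
        return design, np.array([model.to_natural(x)])
    if method == "mcmc":
        cfg = MCMCConfig.reduced(seed=seed, n_chains=2, n_warmup=300, n_samples=300)
        draws = _run_chains(model, cfg)
        return design, draws.theta_matrix(thin=20)
    raise SelectionError(f"unknown fold-fit method {method!r}")


def predict_target(design, theta_set: np.ndarray, test: pd.DataFrame, target: str):
    """Held-out predictions for one fold, averaged over the supplied
    parameter draws (a single MAP point or thinned posterior draws).

    Binary/treatment targets return P(target = 1 | other observed
    pre-treatment variables); the outcome returns a plug-in risk score
    (linear predictor at the latent posterior means).
    """
    dag = design.dag
    model = CollapsedModel(design, design.pack_data(test), quad_fitness=9, quad_behavior=9)
    data = model.data
    preds = np.zeros(data.n)
    for theta in theta_set:
        g = lambda name: theta[model.idx[name]]
        if target == dag.treatment:
            preds += model.propensity(theta)
        elif target in data.y_binary:
            node = next(b for b in design.binary_nodes if b.name == target)
            if node.latent == "fitness":
                uf, r = model.fitness_posterior(
                    theta, include_treatment=True, exclude=(target,)
                )
                eta = g(f"{target}_intercept") + node.sign * g(f"{target}_loading") * uf
                preds += (r * sigmoid(eta)).sum(1)
            elif node.latent == "behavior":
                zb, r = model.behavior_posterior(theta, exclude=(target,))
                eta = g(f"{target}_intercept") + node.sign * g(f"{target}_loading") * zb
                preds += (r * sigmoid(eta)).sum(1)
            else:
                preds += np.full(data.n, sigmoid(g(f"{target}_intercept")))
        elif target == dag.outcome:
            eta = (
                g("outcome_intercept")
                + g("outcome_treatment") * data.A
                + (data.Xo @ theta[model._i_ocovs] if design.outcome_covs else 0.0)
                + data.A * (data.Xi @ theta[model._i_icovs] if design.interaction_covs else 0.0)
            )
            if design.out_on_fitness or design.interaction_fitness:
                uf, r = model.fitness_posterior(theta, include_treatment=True)
                euf = (r * uf).sum(1)
                cf = (g("outcome_fitness") if design.out_on_fitness else 0.0) + (
                    g("interaction_fitness") * data.A if design.interaction_fitness else 0.0
                )
                eta = eta + cf * euf
            if design.out_on_behavior:
                zb, r = model.behavior_posterior(theta)
                eta = eta + g("outcome_behavior") * (r * zb).sum(1)
            preds += eta
        else:
            raise SelectionError(f"cannot predict target {target!r}")
    return preds / len(theta_set)


def _score_fold(preds: np.ndarray, test: pd.DataFrame, target: str, dag: DAGSpec) -> float:
    if target == dag.outcome:
        from .baselines import harrell_c

        return harrell_c(preds, test["time"].to_numpy(), test["event"].to_numpy())
    y = test[target].to_numpy(float)
    p = np.clip(preds, 1e-12, 1 - 1e-12)
    return float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def crossval_score(
    candidate: CandidateModel,
    cohort: pd.DataFrame,
    target: str,
    K: int = 5,
    seed: int = 0,
    method: str = "map",
) -> CVScore:
    """K-fold cross-validated held-out score of one candidate for one
    fitness effect variable: mean log predictive density for binary
    targets, Harrell's concordance for the survival outcome."""
    if target not in allowed_targets(candidate.dag):
        raise SelectionError(
            f"target {target!r} is not an effect variable of fitness; "
            f"allowed: {allowed_targets(candidate.dag)}"
        )
    fold_scores = []
    for fold_i, (tr, te) in enumerate(_folds(len(cohort), K, seed)):
        design, theta_set = _fit_fold(candidate, cohort.iloc[tr], method, seed + fold_i)
        preds = predict_target(design, theta_set, cohort.iloc[te], target)
        fold_scores.append(_score_fold(preds, cohort.iloc[te], target, candidate.dag))
    fold_scores = np.asarray(fold_scores)
    kind = "concordance" if target == candidate.dag.outcome else "lpd"
    return CVScore(float(fold_scores.mean()), fold_scores, kind)


def baseline_dag(dag: DAGSpec) -> DAGSpec:
    """The comparison graph: the same equations with every latent edge
    removed, so each target is regressed on its direct observed causes
    only (intercept-only for a proxy whose sole parent was a latent)."""
    drop = []
    for latent in (dag.latent_fitness, dag.latent_behavior):
        if latent is not None:
            drop.extend((latent, child) for child in dag.children(latent))
    out = dag.without_edges(drop)
    return out


def baseline_score(
    target: str,
    cohort: pd.DataFrame,
    K: int = 5,
    seed: int = 0,
    dag: DAGSpec | None = None,
    method: str = "map",
) -> CVScore:
    """Cross-validated score of the no-latent baseline regression for one
    target, on the same folds as :func:`crossval_score` for a given seed."""
    from .dag import build_nsclc_dag

    dag = dag or build_nsclc_dag()
    base = CandidateModel(baseline_dag(dag), label="baseline")
    return crossval_score(base, cohort, target, K=K, seed=seed, method=method)


def select_and_average(
    candidates: list[CandidateModel],
    cohort: pd.DataFrame,
    K: int = 5,
    seed: int = 0,
    targets: list[str] | None = None,
    method: str = "map",
) -> SelectionReport:
    """Apply the rejection rule and pool the survivors.

    A candidate is accepted iff its CV score beats the baseline by more
    than one fold-level standard error (and the numerical tie tolerance) on
    at least one target.  Pseudo-BMA weights over accepted candidates are
    proportional to exp(total held-out log predictive density across the
    binary targets).
    """
    if not candidates:
        raise SelectionError("at least one candidate required")
    rows = []
    accepted: list[str] = []
    lpd_totals: dict[str, float] = {}
    base_cache: dict[str, CVScore] = {}
    for cand in candidates:
        tg = targets or allowed_targets(cand.dag)
        any_win = False
        total_lpd = 0.0
        for target in tg:
            cand_cv = crossval_score(cand, cohort, target, K=K, seed=seed, method=method)
            if target not in base_cache:
                base_cache[target] = baseline_score(
                    target, cohort, K=K, seed=seed, dag=cand.dag, method=method
                )
            base_cv = base_cache[target]
            diffs = cand_cv.fold_scores - base_cv.fold_scores
            se = float(diffs.std(ddof=1) / np.sqrt(len(diffs))) if len(diffs) > 1 else 0.0
            diff = float(diffs.mean())
            win = diff > max(se, TIE_TOLERANCE)
            any_win = any_win or win
            if cand_cv.kind == "lpd":
                total_lpd += cand_cv.score * len(cohort)
            rows.append(
                {
                    "candidate": cand.label,
                    "target": target,
                    "score": cand_cv.score,
                    "baseline": base_cv.score,
                    "diff": diff,
                    "se": se,
                    "accepted": win,
                }
            )
        if any_win:
            accepted.append(cand.label)
            lpd_totals[cand.label] = total_lpd

    weights: dict[str, float] = {}
    if accepted:
        vals = np.array([lpd_totals[label] for label in accepted])
        w = np.exp(vals - vals.max())
        w /= w.sum()
        weights = dict(zip(accepted, w))
    return SelectionReport(table=pd.DataFrame(rows), accepted=accepted, weights=weights)


def pooled_ate_loghr(weights: dict[str, float], loghr_draws: dict[str, np.ndarray]) -> dict:
    """Bayesian-model-average pooled ATE: a weighted mixture of the
    accepted candidates' per-draw average log hazard ratios."""
    if not weights:
        raise SelectionError("no accepted candidates to pool")
    labels = list(weights)
    w = np.array([weights[l] for l in labels])
    means = np.array([float(np.mean(loghr_draws[l])) for l in labels])
    pooled_mean = float(w @ means)
    stacked = np.concatenate([loghr_draws[l] for l in labels])
    stacked_w = np.concatenate(
        [np.full(len(loghr_draws[l]), weights[l] / len(loghr_draws[l])) for l in labels]
    )
    lo, hi = np.quantile(
        stacked, [0.025, 0.975], weights=stacked_w, method="inverted_cdf"
    )
    return {
        "hr": float(np.exp(pooled_mean)),
        "ci_low": float(np.exp(lo)),
        "ci_high": float(np.exp(hi)),
        "loghr": pooled_mean,
    }
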