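"""Compilation of a DAGSpec into a concrete parametric model layout.

The compiler turns the declarative graph into:

- an ordered parameter layout (names + positivity constraints) for the
  sampler and optimizer;
- packed numpy arrays for a cohort DataFrame (histology expanded into
  dummies, covariate matrices for the treatment and outcome equations).

Fitness proxies are adverse-coded (logit = intercept - loading * U_f with
loading >= 0: a fitter patient has a lower probability of the adverse
finding), behavior proxies aggressive-coded (logit = intercept +
loading * U_b).  An optional extra unobserved confounder U2 with *fixed*
coefficients on the treatment logit and the log-hazard supports the
omitted-confounder sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dag import DAGSpec, HISTOLOGY_DUMMIES, HISTOLOGY_LEVELS
from .params import ParamSet, add_histology_dummies


def _expand(names: Sequence[str], categorical: str | None) -> tuple[str, ...]:
    out: list[str] = []
    for name in names:
        if categorical is not None and name == categorical:
            out.extend(HISTOLOGY_DUMMIES)
        else:
            out.append(name)
    return tuple(out)


@dataclass(frozen=True)
class BinaryNode:
    name: str
    latent: str | None  # "fitness" | "behavior" | None
    sign: int  # multiplier on the latent in the logit
    constrained: bool  # loading restricted to a half-line


@dataclass(frozen=True)
class ModelDesign:
    dag: DAGSpec
    fitness_cause: str | None
    binary_nodes: tuple[BinaryNode, ...]
    categorical: str | None
    categorical_latent: bool
    treatment_covs: tuple[str, ...]
    treat_on_fitness: bool
    outcome_covs: tuple[str, ...]
    out_on_fitness: bool
    out_on_behavior: bool
    interaction_covs: tuple[str, ...]
    interaction_fitness: bool
    has_fitness: bool
    has_behavior: bool
    # fixed-coefficient extra confounder (theta_treatment, theta_outcome)
    extra_confounder: tuple[float, float] | None = None

    # ------------------------------------------------------------------
    @property
    def param_layout(self) -> tuple[tuple[str, bool], ...]:
        """Ordered (name, positive-constrained) pairs."""
        layout: list[tuple[str, bool]] = []
        if self.has_fitness and self.fitness_cause is not None:
            layout.append(("alpha", False))
        for node in self.binary_nodes:
            layout.append((f"{node.name}_intercept", False))
            if node.latent is not None:
                layout.append((f"{node.name}_loading", node.constrained))
        if self.categorical is not None:
            for level in HISTOLOGY_LEVELS[1:]:
                layout.append((f"histology_{level}_intercept", False))
                if self.categorical_latent:
                    layout.append((f"histology_{level}_loading", False))
        layout.append(("treatment_intercept", False))
        if self.treat_on_fitness:
            layout.append(("treatment_fitness", False))
        layout.extend((f"treatment_{c}", False) for c in self.treatment_covs)
        layout.append(("outcome_intercept", False))
        layout.append(("outcome_treatment", False))
        if self.out_on_fitness:
            layout.append(("outcome_fitness", False))
        if self.out_on_behavior:
            layout.append(("outcome_behavior", False))
        layout.extend((f"outcome_{c}", False) for c in self.outcome_covs)
        layout.extend((f"interaction_{c}", False) for c in self.interaction_covs)
        if self.interaction_fitness:
            layout.append(("interaction_fitness", False))
        layout.append(("weibull_shape", True))
        return tuple(layout)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.param_layout)

    @property
    def n_params(self) -> int:
        return len(self.param_layout)

    def pack(self, params: ParamSet | Mapping[str, float]) -> np.ndarray:
        """Parameter vector on the natural scale (missing names default 0,
        except the Weibull shape which defaults to 1)."""
        get = params.get if hasattr(params, "get") else lambda k, d: params[k]
        vec = np.empty(self.n_params)
        for i, (name, _) in enumerate(self.param_layout):
            default = 1.0 if name == "weibull_shape" else 0.0
            vec[i] = get(name, default)
        return vec

    def unpack(self, vec: np.ndarray) -> ParamSet:
        return ParamSet(dict(zip(self.param_names, np.asarray(vec, float))))

    # ------------------------------------------------------------------
    def pack_data(self, cohort: pd.DataFrame) -> "CohortData":
        return CohortData.from_frame(self, cohort)

    def with_extra_confounder(self, theta_t: float, theta_o: float) -> "ModelDesign":
        from dataclasses import replace

        return replace(self, extra_confounder=(float(theta_t), float(theta_o)))


class DesignError(ValueError):
    pass


def compile_design(dag: DAGSpec, extra_confounder: tuple[float, float] | None = None) -> ModelDesign:
    uf = dag.latent_fitness
    ub = dag.latent_behavior
    treat, out = dag.treatment, dag.outcome

    fitness_cause = None
    if uf is not None:
        causes = [p for p in dag.parents(uf) if dag.node(p).role == "cause_of_fitness"]
        if len(causes) > 1:
            raise DesignError("at most one cause-of-fitness covariate supported")
        fitness_cause = causes[0] if causes else None

    categorical = None
    categorical_latent = False
    binary_nodes: list[BinaryNode] = []
    for node in dag.nodes:
        if node.role == "proxy_of_fitness":
            if node.family != "bernoulli_logit":
                raise DesignError(f"fitness proxy {node.name} must be bernoulli_logit")
            linked = uf is not None and dag.has_edge(uf, node.name)
            constrained = linked and dag.sign_constraints.get((uf, node.name)) is not None
            binary_nodes.append(
                BinaryNode(node.name, "fitness" if linked else None, -1, constrained)
            )
        elif node.role == "proxy_of_behavior":
            linked = ub is not None and dag.has_edge(ub, node.name)
            if node.family == "categorical_logit":
                if categorical is not None:
                    raise DesignError("only one categorical proxy supported")
                categorical = node.name
                categorical_latent = linked
            elif node.family == "bernoulli_logit":
                constrained = linked and dag.sign_constraints.get((ub, node.name)) is not None
                binary_nodes.append(
                    BinaryNode(node.name, "behavior" if linked else None, +1, constrained)
                )
            else:
                raise DesignError(f"unsupported family for proxy {node.name}")

    latent_names = {uf, ub}
    treatment_parents = [
        p for p in dag.parents(treat) if p not in latent_names
    ]
    outcome_parents = [
        p
        for p in dag.parents(out)
        if p not in latent_names and p != treat
    ]
    interactions = [m for m in dag.interactions if m != uf]
    interaction_fitness = (
        uf is not None and uf in dag.interactions and dag.has_edge(uf, out)
    )

    treat_on_fitness = uf is not None and dag.has_edge(uf, treat)
    out_on_fitness = uf is not None and dag.has_edge(uf, out)
    out_on_behavior = ub is not None and dag.has_edge(ub, out)
    has_fitness = any(n.latent == "fitness" for n in binary_nodes) or treat_on_fitness or out_on_fitness
    has_behavior = (
        any(n.latent == "behavior" for n in binary_nodes)
        or categorical_latent
        or out_on_behavior
    )

    return ModelDesign(
        dag=dag,
        fitness_cause=fitness_cause,
        binary_nodes=tuple(binary_nodes),
        categorical=categorical,
        categorical_latent=categorical_latent,
        treatment_covs=_expand(treatment_parents, categorical),
        treat_on_fitness=treat_on_fitness,
        outcome_covs=_expand(outcome_parents, categorical),
        out_on_fitness=out_on_fitness,
        out_on_behavior=out_on_behavior,
        interaction_covs=_expand(interactions, categorical),
        interaction_fitness=interaction_fitness,
        has_fitness=has_fitness,
        has_behavior=has_behavior,
        extra_confounder=extra_confounder,
    )


@dataclass
class CohortData:
    """Numpy view of a coded cohort for one model design."""

    n: int
    age: np.ndarray | None  # fitness-cause covariate
    y_binary: dict[str, np.ndarray]  # per binary node, values in [0, 1]
    y_cat: np.ndarray | None  # integer level codes, reference = 0
    A: np.ndarray
    Xt: np.ndarray  # (n, len(treatment_covs))
    Xo: np.ndarray
    Xi: np.ndarray
    time: np.ndarray
    log_time: np.ndarray
    event: np.ndarray

    @classmethod
    def from_frame(cls, design: ModelDesign, cohort: pd.DataFrame) -> "CohortData":
        if len(cohort) == 0:
            raise DesignError("cohort is empty")
        df = add_histology_dummies(cohort) if design.categorical else cohort.copy()
        n = len(df)

        def col(name: str) -> np.ndarray:
            if name not in df.columns:
                raise DesignError(f"cohort is missing column {name!r}")
            arr = np.asarray(df[name], dtype=float)
            if np.isnan(arr).any():
                raise DesignError(
                    f"column {name!r} contains missing values; run impute_and_filter first"
                )
            return arr

        y_binary = {node.name: col(node.name) for node in design.binary_nodes}
        y_cat = None
        if design.categorical is not None:
            labels = df[design.categorical].astype(str)
            bad = set(labels) - set(HISTOLOGY_LEVELS)
            if bad:
                raise DesignError(f"unknown histology labels: {sorted(bad)}")
            y_cat = np.asarray(
                labels.map({lv: i for i, lv in enumerate(HISTOLOGY_LEVELS)}), dtype=int
            )
        stack = lambda names: (
            np.column_stack([col(c) for c in names]) if names else np.empty((n, 0))
        )
        time = col("time")
        if (time <= 0).any():
            raise DesignError("survival times must be positive")
        return cls(
            n=n,
            age=col(design.fitness_cause) if design.fitness_cause else None,
            y_binary=y_binary,
            y_cat=y_cat,
            A=col("treatment"),
            Xt=stack(design.treatment_covs),
            Xo=stack(design.outcome_covs),
            Xi=stack(design.interaction_covs),
            time=time,
            log_time=np.log(time),
            event=col("event"),
        )
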