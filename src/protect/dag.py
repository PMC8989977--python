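"""Behavior-fitness causal DAG declarations.

The scaffold has two continuous latent variables: *fitness* (the overall
health of the patient as implicitly assessed by the treating physician) and
*behavior* (the biological aggressiveness of the tumor).  Neither is
recorded, but each leaves a trace in proxy variables: performance status and
renal function for fitness; weight loss, histology and TNM substage for
behavior.  Fitness confounds the treatment-outcome relationship (it drives
both the intensity of the prescribed treatment and survival), which is why
conventional covariate adjustment fails and the latent variable has to be
reconstructed from its proxies.

:class:`DAGSpec` is a declarative description of one such graph: node roles,
directed edges, distributional families and sign constraints.  It can be
serialized to plain YAML so other cancer settings can be declared without
code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import yaml

ROLES = frozenset(
    {
        "latent_fitness",
        "latent_behavior",
        "cause_of_fitness",
        "proxy_of_fitness",
        "proxy_of_behavior",
        "treatment",
        "outcome",
    }
)
FAMILIES = frozenset({"gaussian", "bernoulli_logit", "categorical_logit", "weibull_ph"})
SIGNS = frozenset({"nonneg", "nonpos"})


class DAGError(ValueError):
    """Raised when a DAG declaration violates a structural invariant."""


@dataclass(frozen=True)
class Node:
    name: str
    role: str
    family: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise DAGError(f"unknown role {self.role!r} for node {self.name!r}")
        if self.family not in FAMILIES:
            raise DAGError(f"unknown family {self.family!r} for node {self.name!r}")


@dataclass(frozen=True)
class DAGSpec:
    """A behavior-fitness graph.

    Parameters
    ----------
    nodes:
        Node declarations (name, role, distributional family).
    edges:
        Directed (parent, child) pairs.
    sign_constraints:
        Mapping from an edge to ``"nonneg"`` or ``"nonpos"``, constraining the
        loading on that edge.  At least one constraint per latent is required
        to anchor the latent's orientation (otherwise flipping the sign of the
        latent and of all its loadings leaves the likelihood unchanged).
    interactions:
        Names of treatment-effect modifiers: each contributes a
        treatment x modifier term to the outcome linear predictor.  The
        latent fitness node may appear here (the non-linear component of the
        individual treatment effect).
    strict:
        When True (default) the full confounder-proxy invariants are
        enforced.  Deliberately misspecified candidates for the model
        selection step (e.g. with the fitness edges deleted) are built with
        ``strict=False``; acyclicity and role uniqueness are still checked.
    """

    nodes: tuple[Node, ...]
    edges: tuple[tuple[str, str], ...]
    sign_constraints: dict[tuple[str, str], str] = field(default_factory=dict)
    interactions: tuple[str, ...] = ()
    strict: bool = True

    def __post_init__(self) -> None:
        self.validate(strict=self.strict)

    # -- basic accessors -------------------------------------------------
    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise DAGError(f"no node named {name!r}")

    def names(self, role: str | None = None) -> list[str]:
        return [n.name for n in self.nodes if role is None or n.role == role]

    def parents(self, name: str) -> list[str]:
        return [p for p, c in self.edges if c == name]

    def children(self, name: str) -> list[str]:
        return [c for p, c in self.edges if p == name]

    def has_edge(self, parent: str, child: str) -> bool:
        return (parent, child) in self.edges

    @property
    def treatment(self) -> str:
        return self.names("treatment")[0]

    @property
    def outcome(self) -> str:
        return self.names("outcome")[0]

    @property
    def latent_fitness(self) -> str | None:
        names = self.names("latent_fitness")
        return names[0] if names else None

    @property
    def latent_behavior(self) -> str | None:
        names = self.names("latent_behavior")
        return names[0] if names else None

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from(self.edges)
        return g

    # -- validation ------------------------------------------------------
    def validate(self, strict: bool = True) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise DAGError("duplicate node names")
        for p, c in self.edges:
            if p not in names or c not in names:
                raise DAGError(f"edge ({p!r}, {c!r}) references an undeclared node")
        if not nx.is_directed_acyclic_graph(self.to_graph()):
            raise DAGError("graph has a directed cycle")
        if len(self.names("treatment")) != 1 or len(self.names("outcome")) != 1:
            raise DAGError("exactly one treatment node and one outcome node required")
        for edge, sign in self.sign_constraints.items():
            if tuple(edge) not in self.edges:
                raise DAGError(f"sign constraint on non-existent edge {edge}")
            if sign not in SIGNS:
                raise DAGError(f"unknown sign {sign!r}")
        for m in self.interactions:
            if m not in names:
                raise DAGError(f"interaction modifier {m!r} is not a node")
        if not strict:
            return

        treat, out = self.treatment, self.outcome
        uf = self.latent_fitness
        ub = self.latent_behavior
        if uf is None:
            raise DAGError("strict DAG requires a latent_fitness node")
        # fitness is a confounder: parent of both treatment and outcome
        if not (self.has_edge(uf, treat) and self.has_edge(uf, out)):
            raise DAGError("latent fitness must be a parent of treatment and outcome")
        for proxy in self.names("proxy_of_fitness"):
            if uf not in self.parents(proxy):
                raise DAGError(f"fitness proxy {proxy!r} lacks the fitness parent")
            if treat in self.children(proxy) or out in self.children(proxy):
                raise DAGError(
                    f"proxy {proxy!r} may not be a parent of treatment or outcome"
                )
        if ub is not None:
            if not self.has_edge(ub, out):
                raise DAGError("latent behavior must be a parent of the outcome")
            for proxy in self.names("proxy_of_behavior"):
                if ub not in self.parents(proxy):
                    raise DAGError(f"behavior proxy {proxy!r} lacks the behavior parent")
        for latent in filter(None, (uf, ub)):
            anchored = any(
                edge[0] == latent for edge in self.sign_constraints
            )
            if not anchored:
                raise DAGError(
                    f"latent {latent!r} has no sign constraint anchoring its orientation"
                )

    # -- derived structure -----------------------------------------------
    def is_confounder(self, latent: str) -> bool:
        """True iff ``latent`` is a parent of both treatment and outcome."""
        ch = set(self.children(latent))
        return self.treatment in ch and self.outcome in ch

    def backdoor_latents(self) -> list[str]:
        """Latent nodes that open a back-door path from treatment to outcome."""
        return [
            n.name
            for n in self.nodes
            if n.role.startswith("latent") and self.is_confounder(n.name)
        ]

    # -- variants (for candidate models and sensitivity analyses) ---------
    def without_edges(self, drop: Iterable[tuple[str, str]]) -> "DAGSpec":
        drop = {tuple(e) for e in drop}
        return replace(
            self,
            edges=tuple(e for e in self.edges if e not in drop),
            sign_constraints={
                e: s for e, s in self.sign_constraints.items() if e not in drop
            },
            strict=False,
        )

    def without_node(self, name: str) -> "DAGSpec":
        return replace(
            self,
            nodes=tuple(n for n in self.nodes if n.name != name),
            edges=tuple(e for e in self.edges if name not in e),
            sign_constraints={
                e: s for e, s in self.sign_constraints.items() if name not in e
            },
            interactions=tuple(m for m in self.interactions if m != name),
            strict=False,
        )

    # -- serialization ----------------------------------------------------
    def to_yaml(self) -> str:
        payload = {
            "nodes": [[n.name, n.role, n.family] for n in self.nodes],
            "edges": [list(e) for e in self.edges],
            "sign_constraints": [[list(e), s] for e, s in self.sign_constraints.items()],
            "interactions": list(self.interactions),
            "strict": self.strict,
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DAGSpec":
        payload = yaml.safe_load(text)
        return cls(
            nodes=tuple(Node(*n) for n in payload["nodes"]),
            edges=tuple(tuple(e) for e in payload["edges"]),
            sign_constraints={
                tuple(e): s for e, s in payload.get("sign_constraints", [])
            },
            interactions=tuple(payload.get("interactions", ())),
            strict=payload.get("strict", True),
        )


HISTOLOGY_LEVELS = ("adeno", "squamous", "other")
HISTOLOGY_DUMMIES = ("hist_squamous", "hist_other")


def build_nsclc_dag() -> DAGSpec:
    """Reference DAG for stage III NSCLC: concurrent vs sequential chemoradiation.

    Structure: age -> fitness; fitness -> {performance status, renal function,
    treatment, survival}; behavior -> {weight loss, histology, substage,
    survival}; the observed tumor markers and age are additional parents of
    the treatment decision; the outcome depends on treatment, both latents,
    the observed covariates and treatment x modifier interactions.

    The loading of fitness on performance status is constrained nonnegative
    (a fitter patient has a *lower* probability of ECOG >= 1 under the
    adverse-coded parameterization), which anchors the orientation of the
    fitness axis; the remaining proxy loadings carry the same monotone
    constraints.
    """
    nodes = (
        Node("fitness", "latent_fitness", "gaussian"),
        Node("behavior", "latent_behavior", "gaussian"),
        Node("age_z", "cause_of_fitness", "gaussian"),
        Node("ps_geq1", "proxy_of_fitness", "bernoulli_logit"),
        Node("egfr_lt60", "proxy_of_fitness", "bernoulli_logit"),
        Node("weight_loss", "proxy_of_behavior", "bernoulli_logit"),
        Node("stage_iiib_c", "proxy_of_behavior", "bernoulli_logit"),
        Node("histology", "proxy_of_behavior", "categorical_logit"),
        Node("treatment", "treatment", "bernoulli_logit"),
        Node("survival", "outcome", "weibull_ph"),
    )
    edges = (
        ("age_z", "fitness"),
        ("fitness", "ps_geq1"),
        ("fitness", "egfr_lt60"),
        ("fitness", "treatment"),
        ("fitness", "survival"),
        ("behavior", "weight_loss"),
        ("behavior", "stage_iiib_c"),
        ("behavior", "histology"),
        ("behavior", "survival"),
        ("stage_iiib_c", "treatment"),
        ("histology", "treatment"),
        ("weight_loss", "treatment"),
        ("age_z", "treatment"),
        ("treatment", "survival"),
        ("age_z", "survival"),
        ("stage_iiib_c", "survival"),
        ("histology", "survival"),
        ("weight_loss", "survival"),
    )
    sign_constraints = {
        ("fitness", "ps_geq1"): "nonneg",
        ("fitness", "egfr_lt60"): "nonneg",
        ("behavior", "weight_loss"): "nonneg",
        ("behavior", "stage_iiib_c"): "nonneg",
    }
    interactions = ("age_z", "stage_iiib_c", "weight_loss", "histology", "fitness")
    return DAGSpec(nodes, edges, sign_constraints, interactions)
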