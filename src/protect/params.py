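"""Structural-equation parameters, priors and the patient-level record."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .dag import HISTOLOGY_LEVELS


class ParamError(ValueError):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors, scale-matched to standardized covariates.

    Normal(0, ``scale_coef``^2) on unconstrained coefficients and intercepts,
    Half-Normal(``scale_loading``) on sign-constrained proxy loadings and
    Half-Normal(``scale_shape``) on the Weibull shape.
    """

    scale_coef: float = 2.5
    scale_loading: float = 1.0
    scale_shape: float = 1.0


class ParamSet(Mapping[str, float]):
    """One full assignment of structural-equation parameters, keyed by name.

    Naming convention (matching :func:`protect.dag.build_nsclc_dag`):

    - ``alpha`` — slope of latent fitness on standardized age;
    - ``<proxy>_intercept`` / ``<proxy>_loading`` — logit intercept and latent
      loading of a binary proxy (fitness proxies are adverse-coded: the
      linear predictor is ``intercept - loading * U_f``; behavior proxies use
      ``intercept + loading * U_b``);
    - ``histology_<level>_intercept`` / ``_loading`` — categorical-logit
      coefficients per non-reference histology level (reference: adeno);
    - ``treatment_intercept``, ``treatment_fitness``, ``treatment_<cov>`` —
      treatment-decision logit;
    - ``outcome_intercept``, ``outcome_treatment`` (the main-effect
      log-hazard ratio), ``outcome_fitness``, ``outcome_behavior``,
      ``outcome_<cov>``, ``interaction_<cov>``, ``interaction_fitness`` —
      proportional-hazards linear predictor;
    - ``weibull_shape`` — baseline-hazard shape ``k > 0`` (``k = 1`` is the
      exponential model).

    Latent scales are fixed at 1 for location-scale identifiability.
    """

    def __init__(self, values: Mapping[str, float]):
        self._values = {str(k): float(v) for k, v in values.items()}
        k = self._values.get("weibull_shape")
        if k is not None and k <= 0:
            raise ParamError(f"weibull_shape must be positive, got {k}")

    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def get(self, key: str, default: float = 0.0) -> float:
        return self._values.get(key, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"ParamSet({self._values!r})"

    def replace(self, **updates: float) -> "ParamSet":
        merged = dict(self._values)
        merged.update(updates)
        return ParamSet(merged)

    @property
    def shape(self) -> float:
        return self._values.get("weibull_shape", 1.0)

    def as_dict(self) -> dict[str, float]:
        return dict(self._values)


@dataclass
class PatientRecord:
    """One patient's coded pre-treatment covariates, treatment and outcome.

    ``weight_loss`` may be None (missing) before the imputation/filter step;
    binary fields may carry the fractional value 0.5 after imputation.
    """

    age_z: float
    ps_geq1: float
    egfr_lt60: float
    weight_loss: float | None
    histology: str
    stage_iiib_c: float
    treatment: int
    time: float
    event: int
    switch: int | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ParamError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ParamError(f"event indicator must be 0 or 1, got {self.event}")
        if self.histology not in HISTOLOGY_LEVELS:
            raise ParamError(
                f"histology {self.histology!r} not one of {HISTOLOGY_LEVELS}"
            )


COHORT_COLUMNS = (
    "age_z",
    "ps_geq1",
    "egfr_lt60",
    "weight_loss",
    "histology",
    "stage_iiib_c",
    "treatment",
    "time",
    "event",
)


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    if df["switch"].isna().all():
        df = df.drop(columns=["switch"])
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        wl = d.get("weight_loss")
        out.append(
            PatientRecord(
                age_z=d["age_z"],
                ps_geq1=d["ps_geq1"],
                egfr_lt60=d["egfr_lt60"],
                weight_loss=None if wl is None or (isinstance(wl, float) and math.isnan(wl)) else wl,
                histology=d["histology"],
                stage_iiib_c=d["stage_iiib_c"],
                treatment=int(d["treatment"]),
                time=float(d["time"]),
                event=int(d["event"]),
                switch=None if "switch" not in d or pd.isna(d["switch"]) else int(d["switch"]),
            )
        )
    return out


def add_histology_dummies(df: pd.DataFrame) -> pd.DataFrame:
    """Materialize the two histology dummies (adenocarcinoma reference)."""
    df = df.copy()
    df["hist_squamous"] = (df["histology"] == "squamous").astype(float)
    df["hist_other"] = (df["histology"] == "other").astype(float)
    return df
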