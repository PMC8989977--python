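"""Cohort input/output: the chart-level record, coding rules and the
missing-data policy.

Coding rules: any weight loss means more than 3% of original body weight
over the six months before the treatment decision; performance status is
dichotomized ECOG 0 versus 1 or higher; renal function is dichotomized at
an eGFR of 60 ml/min/1.73 m^2; substage IIIA versus IIIB/IIIC.  Follow-up
starts at the last multi-disciplinary tumor board meeting before treatment
start (the moment the treatment decision is made).

Missing-data policy: variables with under 5% missing entries are imputed —
observed mean for continuous variables, the fixed fractional value 0.5 for
binary variables (carried into the likelihood as a covariate value, not
resampled) — while rows with missing weight loss are dropped entirely:
weight loss is plausibly recorded more often when present, a pattern under
which complete-case analysis is unbiased and imputation is not.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .dag import HISTOLOGY_LEVELS
from .params import COHORT_COLUMNS, PatientRecord

DAYS_PER_YEAR = 365.25
TREATMENT_LABELS = {"concurrent": 1, "sequential": 0}
SUBSTAGES = ("IIIA", "IIIB", "IIIC")
BINARY_COLUMNS = ("ps_geq1", "egfr_lt60", "stage_iiib_c")
MAX_MISSING_FRACTION = 0.05


class IOError_(ValueError):
    pass


@dataclass
class RawRecord:
    """One patient's chart-level values before coding."""

    age_years: float
    ecog: int | None
    egfr_value: float | None
    weight_loss_percent: float | None
    histology_label: str | None
    tnm_substage: str
    treatment_label: str
    tumor_board_date: date | None
    treatment_start_date: date
    last_followup_or_death_date: date
    died: int

    def __post_init__(self) -> None:
        if self.tumor_board_date is not None:
            if not (self.tumor_board_date <= self.treatment_start_date):
                raise IOError_("tumor board date must precede treatment start")
            if not (self.treatment_start_date <= self.last_followup_or_death_date):
                raise IOError_("treatment start must precede last follow-up")


def encode_covariates(
    raw: RawRecord, age_mean: float = 0.0, age_sd: float = 1.0
) -> PatientRecord:
    """Apply the coding rules to one chart record.

    Missing chart values propagate as missing coded values (NaN); survival
    time is measured in years from the tumor board date.
    """
    if raw.tnm_substage not in SUBSTAGES:
        raise IOError_(
            f"unparseable substage {raw.tnm_substage!r}; accepted: {SUBSTAGES}"
        )
    if raw.treatment_label not in TREATMENT_LABELS:
        raise IOError_(
            f"unparseable treatment {raw.treatment_label!r}; accepted: "
            f"{tuple(TREATMENT_LABELS)}"
        )
    if raw.histology_label is not None and raw.histology_label not in HISTOLOGY_LEVELS:
        raise IOError_(
            f"unparseable histology {raw.histology_label!r}; accepted: {HISTOLOGY_LEVELS}"
        )
    if raw.tumor_board_date is None:
        raise IOError_("tumor board date missing; impute it at the cohort level first")
    time = (raw.last_followup_or_death_date - raw.tumor_board_date).days / DAYS_PER_YEAR
    return PatientRecord(
        age_z=(raw.age_years - age_mean) / age_sd,
        ps_geq1=np.nan if raw.ecog is None else float(raw.ecog >= 1),
        egfr_lt60=np.nan if raw.egfr_value is None else float(raw.egfr_value < 60.0),
        weight_loss=(
            None if raw.weight_loss_percent is None else float(raw.weight_loss_percent > 3.0)
        ),
        histology=raw.histology_label if raw.histology_label is not None else "adeno",
        stage_iiib_c=float(raw.tnm_substage in ("IIIB", "IIIC")),
        treatment=TREATMENT_LABELS[raw.treatment_label],
        time=max(time, 1.0 / DAYS_PER_YEAR),
        event=int(raw.died),
    )


def impute_tumor_board_dates(raw: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill missing tumor board dates from the treatment start date minus
    the mean decision-to-treatment gap of the patient's treatment group."""
    df = raw.copy()
    for col in ("tumor_board_date", "treatment_start_date", "last_followup_or_death_date"):
        df[col] = pd.to_datetime(df[col])
    missing = df["tumor_board_date"].isna()
    if not missing.any():
        return df, 0
    gap = (df["treatment_start_date"] - df["tumor_board_date"]).dt.days
    mean_gap = gap.groupby(df["treatment_label"]).mean()
    fill = df["treatment_start_date"] - pd.to_timedelta(
        df["treatment_label"].map(mean_gap).round(), unit="D"
    )
    df.loc[missing, "tumor_board_date"] = fill[missing]
    return df, int(missing.sum())


def encode_cohort(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Code a chart-level cohort table; age is standardized by the analysis
    sample's mean and standard deviation."""
    raw, n_dates = impute_tumor_board_dates(raw)
    age_mean = float(raw["age_years"].mean())
    age_sd = float(raw["age_years"].std(ddof=0)) or 1.0
    records = []
    for row in raw.to_dict("records"):
        rec = encode_covariates(
            RawRecord(
                age_years=float(row["age_years"]),
                ecog=None if pd.isna(row["ecog"]) else int(row["ecog"]),
                egfr_value=None if pd.isna(row["egfr_value"]) else float(row["egfr_value"]),
                weight_loss_percent=(
                    None
                    if pd.isna(row["weight_loss_percent"])
                    else float(row["weight_loss_percent"])
                ),
                histology_label=(
                    None if pd.isna(row["histology_label"]) else str(row["histology_label"])
                ),
                tnm_substage=str(row["tnm_substage"]),
                treatment_label=str(row["treatment_label"]),
                tumor_board_date=row["tumor_board_date"].date(),
                treatment_start_date=row["treatment_start_date"].date(),
                last_followup_or_death_date=row["last_followup_or_death_date"].date(),
                died=int(row["died"]),
            ),
            age_mean=age_mean,
            age_sd=age_sd,
        )
        d = rec.__dict__.copy()
        d["weight_loss"] = np.nan if rec.weight_loss is None else rec.weight_loss
        records.append(d)
    coded = pd.DataFrame(records).drop(columns=["switch"])
    if "histology_label" in raw.columns:
        coded.loc[raw["histology_label"].isna().to_numpy(), "histology"] = np.nan
    report = {"tumor_board_dates_imputed": n_dates, "age_mean": age_mean, "age_sd": age_sd}
    return coded, report


def impute_and_filter(
    cohort: pd.DataFrame, allow_high_missingness: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Apply the missing-data policy to a coded cohort.

    Rows with missing weight loss are dropped (complete-case rule); other
    variables with under 5% missing entries are imputed (mean for age,
    the fixed value 0.5 for binary indicators, the modal level for
    histology).  A non-weight-loss variable at or above 5% missing raises
    unless ``allow_high_missingness`` is set (an explicit policy choice).
    """
    df = cohort.copy()
    report: dict[str, int] = {}

    wl_missing = df["weight_loss"].isna()
    report["excluded_missing_weight_loss"] = int(wl_missing.sum())
    df = df[~wl_missing].copy()
    if len(df) == 0:
        raise IOError_("all rows excluded: weight loss entirely missing")

    def check_fraction(col: str, frac: float) -> None:
        if frac >= MAX_MISSING_FRACTION and not allow_high_missingness:
            raise IOError_(
                f"{col} has {100 * frac:.1f}% missing (>= 5%); pass "
                "allow_high_missingness=True to impute anyway"
            )

    for col in BINARY_COLUMNS:
        miss = df[col].isna()
        frac = miss.mean()
        check_fraction(col, frac)
        df.loc[miss, col] = 0.5
        report[f"imputed_{col}"] = int(miss.sum())

    miss = df["age_z"].isna()
    check_fraction("age_z", miss.mean())
    df.loc[miss, "age_z"] = df["age_z"].mean()
    report["imputed_age_z"] = int(miss.sum())

    miss = df["histology"].isna()
    check_fraction("histology", miss.mean())
    if miss.any():
        df.loc[miss, "histology"] = df["histology"].mode().iloc[0]
    report["imputed_histology"] = int(miss.sum())

    for col in ("treatment", "time", "event"):
        if df[col].isna().any():
            raise IOError_(f"missing values in required column {col!r}")
    return df.reset_index(drop=True), report


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Plain CSV: header row, comma separator, UTF-8, empty string for
    missing values."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"cohort CSV lacks columns: {missing}")
    return df


def write_truth_json(truth, path, seed: int | None = None) -> None:
    """Sidecar file with the simulation ground truth."""
    import json

    payload = {
        "seed": seed,
        "params": truth.params.as_dict(),
        "true_ate_loghr": truth.true_ate_loghr,
        "true_ite_loghr": truth.true_ite_loghr.tolist(),
        "latents": truth.latents.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
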