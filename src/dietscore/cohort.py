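"""Cohort assembly: eligibility filters, derived variables and covariate coding.

The analytic sample is women of reproductive age (20-45 years) with
complete diet-score components, outcomes (self-reported infertility,
SHBG, total testosterone, estradiol) and mediators (BMI, waist
circumference).  Exclusions are applied sequentially and counted so a
participant-flow chart can be reconstructed.

Derived quantities: HOMA-IR insulin-resistance index, obesity and
high-waist-circumference indicators (boundary-inclusive at 30 kg/m^2 and
88 cm), and survey-weighted median dichotomisation of the continuous
hormone outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .survey import weighted_median

__all__ = [
    "AnalyticCohort",
    "apply_exclusions",
    "homa_ir",
    "classify_obesity",
    "classify_wc",
    "dichotomize_at_median",
    "code_covariates",
    "read_table",
    "CATEGORY_LEVELS",
    "CORE_COVARIATES",
    "EXTENDED_COVARIATES",
    "OUTCOME_MEDIATOR_COLUMNS",
]

#: columns whose missingness triggers the outcome/mediator exclusion step
OUTCOME_MEDIATOR_COLUMNS = ("infertility", "shbg", "tt", "e2", "bmi", "wc")

#: categorical codings; the first level of each is the model reference
CATEGORY_LEVELS: dict[str, list[str]] = {
    "race": ["nonhispanic_white", "nonhispanic_black", "mexican_american", "other"],
    "education": [
        "below_high_school",
        "high_school",
        "some_college",
        "college_graduate",
    ],
    "marital": ["married_or_partner", "live_alone"],
    "pir_cat": ["lt1", "ge1", "miss"],
    "smoking": ["never", "former", "current"],
    "physical_activity": ["ge600", "lt600"],
}

CORE_COVARIATES = (
    "age",
    "race",
    "education",
    "marital",
    "pir_cat",
    "smoking",
    "physical_activity",
    "total_energy_kcal",
)
EXTENDED_COVARIATES = CORE_COVARIATES + (
    "total_cholesterol",
    "triglyceride",
    "ldl",
    "hdl",
    "homa_ir",
)


def read_table(path: str | Path, varmap: str | Path | dict | None = None) -> pd.DataFrame:
    """Read a participant table from CSV or SAS transport (XPT).

    ``varmap`` maps source variable names (e.g. NHANES codebook names
    such as RHQ074, BMXBMI, WTDRD1) to the internal field names used
    throughout this package; it may be a dict or a YAML file of the form
    ``{source_name: internal_name}``.
    """
    path = Path(path)
    if path.suffix.lower() == ".xpt":
        df = pd.read_sas(path, format="xport")
    else:
        df = pd.read_csv(path)
    if varmap is not None:
        if not isinstance(varmap, dict):
            with open(varmap) as fh:
                varmap = yaml.safe_load(fh)
        df = df.rename(columns=varmap)
    return df


@dataclass(frozen=True)
class AnalyticCohort:
    """Filtered records plus the per-step exclusion counts, in order."""

    records: pd.DataFrame
    exclusion_log: dict[str, int]
    n_input: int

    def __post_init__(self) -> None:
        if sum(self.exclusion_log.values()) != self.n_input - len(self.records):
            raise ValueError("exclusion counts do not reconcile with output size")

    @property
    def n(self) -> int:
        return len(self.records)


def apply_exclusions(
    records: pd.DataFrame, diet_components: Sequence[str]
) -> AnalyticCohort:
    """Apply the eligibility filters sequentially and log counts.

    Order: (a) males, (b) age under 20 or over 45, (c) missing any active
    diet-score component, (d) missing any outcome or mediator.  An empty
    result is allowed (callers should check ``cohort.n``).
    """
    df = records
    n_input = len(df)
    log: dict[str, int] = {}

    if "sex" in df.columns:
        keep = df["sex"].astype(str).str.lower().isin(["female", "f", "2", "2.0"])
    else:
        keep = pd.Series(True, index=df.index)
    log["male"] = int((~keep).sum())
    df = df[keep]

    keep = (df["age"] >= 20) & (df["age"] <= 45)
    log["age_out_of_range"] = int((~keep).sum())
    df = df[keep]

    present = [c for c in diet_components if c in df.columns]
    absent = [c for c in diet_components if c not in df.columns]
    if absent:
        raise KeyError(f"diet components missing from table: {absent}")
    keep = df[present].notna().all(axis=1)
    log["missing_diet_components"] = int((~keep).sum())
    df = df[keep]

    outcome_cols = [c for c in OUTCOME_MEDIATOR_COLUMNS if c in df.columns]
    keep = df[outcome_cols].notna().all(axis=1)
    log["missing_outcome_or_mediator"] = int((~keep).sum())
    df = df[keep]

    return AnalyticCohort(df.reset_index(drop=True), log, n_input)


def homa_ir(
    insulin: float | np.ndarray | pd.Series, glucose: float | np.ndarray | pd.Series
) -> float | np.ndarray:
    """HOMA-IR = fasting insulin (mU/L) x fasting glucose (mmol/L) / 22.5."""
    ins = np.asarray(insulin, dtype=float)
    glu = np.asarray(glucose, dtype=float)
    if (ins < 0).any() or (glu < 0).any():
        raise ValueError("insulin and glucose must be non-negative")
    out = ins * glu / 22.5
    return float(out) if out.ndim == 0 else out


def classify_obesity(bmi: float | np.ndarray | pd.Series) -> np.ndarray | str:
    """'obese' at BMI >= 30.0 kg/m^2 (boundary inclusive), else 'nonobese'."""
    b = np.asarray(bmi, dtype=float)
    if (b <= 0).any():
        raise ValueError("bmi must be positive")
    out = np.where(b >= 30.0, "obese", "nonobese")
    return str(out) if out.ndim == 0 else out


def classify_wc(wc: float | np.ndarray | pd.Series) -> np.ndarray | str:
    """'high_wc' at waist circumference >= 88 cm, else 'normal'."""
    w = np.asarray(wc, dtype=float)
    if (w <= 0).any():
        raise ValueError("wc must be positive")
    out = np.where(w >= 88.0, "high_wc", "normal")
    return str(out) if out.ndim == 0 else out


def dichotomize_at_median(
    values: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series | None = None,
) -> tuple[np.ndarray, float]:
    """Split at the (survey-weighted) median: 1 above the cutpoint, 0 at
    or below it.  Returns ``(labels, cutpoint)``.

    The weighted median is the default because the weights carry the
    survey's representativeness; pass ``weights=None`` for the unweighted
    split.  Values exactly at the cutpoint go to the low group.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.isfinite(v).all():
        raise ValueError("need at least 2 finite values")
    if np.ptp(v) == 0:
        raise ValueError("all values identical: median split undefined")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    cut = weighted_median(v, w)
    return (v > cut).astype(int), float(cut)


def _categorise(series: pd.Series, levels: list[str], name: str) -> pd.Categorical:
    vals = series.astype(str)
    unknown = set(vals.dropna()) - set(levels) - {"nan"}
    if unknown:
        raise ValueError(f"unknown {name} codes: {sorted(unknown)}")
    return pd.Categorical(vals, categories=levels)


def code_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Model-ready covariate codings.

    Categorical covariates are coerced to fixed level orders (the first
    level is the regression reference).  PIR is coded <1 / >=1 with an
    explicit 'miss' level so missing income never drops a participant;
    physical activity is dichotomised at 600 MET-minutes/week (boundary
    inclusive in the active group).  HOMA-IR is derived when fasting
    insulin and glucose are present.  Continuous covariates pass through.
    """
    df = records.copy()
    if "pir" in df.columns and "pir_cat" not in df.columns:
        pir = pd.to_numeric(df["pir"], errors="coerce")
        df["pir_cat"] = np.where(
            pir.isna(), "miss", np.where(pir < 1.0, "lt1", "ge1")
        )
    if "physical_activity_met" in df.columns and "physical_activity" not in df.columns:
        met = pd.to_numeric(df["physical_activity_met"], errors="coerce")
        df["physical_activity"] = np.where(met >= 600.0, "ge600", "lt600")
    if (
        "homa_ir" not in df.columns
        and {"fasting_insulin", "fasting_glucose"} <= set(df.columns)
    ):
        df["homa_ir"] = homa_ir(df["fasting_insulin"], df["fasting_glucose"])
    for name, levels in CATEGORY_LEVELS.items():
        if name in df.columns:
            df[name] = _categorise(df[name], levels, name)
    return df
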