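"""Eligibility filters, recodings and weight trimming for survey and registry tables.

The survey table keeps respondents aged 25+ living in one of the 13 registry
states, dropping mixed-race records (the registry has no matching race code).
The registry table keeps cancer cases aged 35+ diagnosed 2001-2015.  Sampling
weights are trimmed at the 0.5th/99.5th empirical percentiles before each
behavior-model fit.  Every removed row is attributed to exactly one filter in a
:class:`PrepReport`.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "PrepReport",
    "filter_survey",
    "filter_registry",
    "trim_extreme_weights",
    "recode_stage",
    "discretize_survival",
    "encode_year",
    "YEAR_MIN",
    "YEAR_MAX",
    "DAYS_PER_MONTH",
    "MAX_SURVIVAL_MONTHS",
    "STATES",
    "SEXES",
    "RACES",
    "RACES_WITH_MIXED",
    "MARITAL_STATUSES",
    "STAGES",
    "STAGE_UNAVAILABLE",
]

#: Study period covered by both data sources.
YEAR_MIN, YEAR_MAX = 2001, 2015

#: One month of survival time, in days (365/12 rounded to one decimal).
DAYS_PER_MONTH = 30.4

#: Longest recordable survival, in whole months.
MAX_SURVIVAL_MONTHS = 179

#: Minimum 5-year age-band index for survey eligibility (band 5 = ages 25-29).
SURVEY_MIN_AGE_BAND = 5
#: Minimum 5-year age-band index for registry eligibility (band 7 = ages 35-39).
REGISTRY_MIN_AGE_BAND = 7

#: The 13 states covered by the cancer registries (reference level first).
STATES = (
    "California",
    "Alaska",
    "Connecticut",
    "Georgia",
    "Hawaii",
    "Iowa",
    "Kentucky",
    "Louisiana",
    "Michigan",
    "New Jersey",
    "New Mexico",
    "Utah",
    "Washington",
)

SEXES = ("male", "female")
RACES = ("White", "Black", "Asian/PI", "AI/AN")
RACES_WITH_MIXED = RACES + ("mixed",)
MARITAL_STATUSES = ("married", "divorced/separated", "widowed", "single")

#: Stage categories used in adjusted models (reference level first).
STAGES = ("I", "II", "III", "IV", "not_specified")
#: Sentinel for diagnoses before stage recording began in 2004.
STAGE_UNAVAILABLE = "unavailable_pre2004"
STAGE_RECORDING_START = 2004


class SchemaError(ValueError):
    """An input table violates the documented schema (unknown label, missing column)."""


@dataclass
class PrepReport:
    """Bookkeeping for one filtering step: every removed row is counted once."""

    rows_in: int
    rows_out: int
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rows_in < 0 or self.rows_out < 0 or any(v < 0 for v in self.exclusions.values()):
            raise ValueError("PrepReport counts must be non-negative")
        if self.rows_out + sum(self.exclusions.values()) != self.rows_in:
            raise ValueError("PrepReport does not balance: rows_out + exclusions != rows_in")

    def to_json(self) -> str:
        return json.dumps(
            {"rows_in": self.rows_in, "rows_out": self.rows_out, "exclusions": self.exclusions}
        )


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing columns: {missing}")


def _check_labels(df: pd.DataFrame, column: str, allowed: tuple[str, ...]) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unknown label {df[column].iloc[row]!r} in column {column!r} (first at row {row}); "
            f"allowed: {list(allowed)}"
        )


def filter_survey(df: pd.DataFrame) -> tuple[pd.DataFrame, PrepReport]:
    """Apply survey eligibility: year 2001-2015, age 25+, 13 states, race not mixed.

    Filters are applied in the order year -> age -> state -> race so each
    removed row is attributed to exactly one cause.
    """
    _require_columns(df, ["year", "age_group", "sex", "race", "marital", "state"], "survey")
    _check_labels(df, "sex", SEXES)
    _check_labels(df, "race", RACES_WITH_MIXED)
    _check_labels(df, "marital", MARITAL_STATUSES)

    rows_in = len(df)
    exclusions: dict[str, int] = {}

    keep = df["year"].between(YEAR_MIN, YEAR_MAX)
    exclusions["year"] = int((~keep).sum())
    df = df[keep]

    keep = df["age_group"] >= SURVEY_MIN_AGE_BAND
    exclusions["age_under_25"] = int((~keep).sum())
    df = df[keep]

    keep = df["state"].isin(STATES)
    exclusions["state"] = int((~keep).sum())
    df = df[keep]

    keep = df["race"] != "mixed"
    exclusions["race_mixed"] = int((~keep).sum())
    df = df[keep]

    report = PrepReport(rows_in=rows_in, rows_out=len(df), exclusions=exclusions)
    logger.info("filter_survey: %s", report.to_json())
    return df.reset_index(drop=True), report


def filter_registry(df: pd.DataFrame) -> tuple[pd.DataFrame, PrepReport]:
    """Apply registry eligibility: diagnosis year 2001-2015 and age 35+ at diagnosis."""
    _require_columns(df, ["year", "age_group", "sex", "race", "marital", "state"], "registry")
    _check_labels(df, "sex", SEXES)
    _check_labels(df, "race", RACES)
    _check_labels(df, "marital", MARITAL_STATUSES)

    rows_in = len(df)
    exclusions: dict[str, int] = {}

    keep = df["year"].between(YEAR_MIN, YEAR_MAX)
    exclusions["year"] = int((~keep).sum())
    df = df[keep]

    keep = df["age_group"] >= REGISTRY_MIN_AGE_BAND
    exclusions["age_under_35"] = int((~keep).sum())
    df = df[keep]

    report = PrepReport(rows_in=rows_in, rows_out=len(df), exclusions=exclusions)
    logger.info("filter_registry: %s", report.to_json())
    return df.reset_index(drop=True), report


def trim_extreme_weights(
    df: pd.DataFrame, weight_col: str = "weight"
) -> tuple[pd.DataFrame, PrepReport]:
    """Drop rows whose sampling weight falls strictly below the 0.5th or strictly
    above the 99.5th empirical percentile.

    Percentiles use the linear-interpolation empirical quantile; ties at the
    threshold are retained, so at most ceil(0.005 n) rows leave each tail.  A
    degenerate (all-equal) weight distribution removes nothing.
    """
    _require_columns(df, [weight_col], "survey")
    w = df[weight_col].to_numpy(dtype=float)
    if len(w) and (w <= 0).any():
        raise ValueError("sampling weights must be positive")
    rows_in = len(df)

    if rows_in == 0 or np.ptp(w) == 0.0:
        if rows_in:
            logger.warning("trim_extreme_weights: degenerate weight distribution, nothing trimmed")
        report = PrepReport(rows_in, rows_in, {"weight_low": 0, "weight_high": 0})
        return df.reset_index(drop=True), report

    lo, hi = np.quantile(w, [0.005, 0.995])
    low = w < lo
    high = w > hi
    report = PrepReport(
        rows_in,
        rows_in - int(low.sum()) - int(high.sum()),
        {"weight_low": int(low.sum()), "weight_high": int(high.sum())},
    )
    logger.info("trim_extreme_weights: %s", report.to_json())
    return df[~(low | high)].reset_index(drop=True), report


def recode_stage(df: pd.DataFrame, stage_col: str = "stage") -> pd.DataFrame:
    """Recode stage at diagnosis to the 5-category scheme from 2004 onwards.

    Diagnoses before 2004 (no stage recording) become ``unavailable_pre2004``
    regardless of input; from 2004 onwards, missing values become
    ``not_specified`` and the I/II/III/IV/not_specified labels pass through.
    """
    _require_columns(df, ["year", stage_col], "registry")
    out = df.copy()
    stage = out[stage_col]

    known = STAGES + (STAGE_UNAVAILABLE,)
    bad = stage.notna() & ~stage.isin(known)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"unmappable stage code {stage.iloc[row]!r} at row {row}; allowed: {list(known)}"
        )

    pre2004 = out["year"] < STAGE_RECORDING_START
    stage = stage.where(stage.notna(), "not_specified")
    stage = stage.mask(pre2004, STAGE_UNAVAILABLE)
    out[stage_col] = stage
    return out


def discretize_survival(days):
    """Convert survival in days to whole months: floor(days / 30.4), capped at 179.

    Deaths within the first 30.4 days count as 0 months.  Accepts scalars or
    arrays; negative input raises ``ValueError``.
    """
    arr = np.asarray(days, dtype=float)
    if (arr < 0).any():
        raise ValueError("survival days must be non-negative")
    months = np.minimum(np.floor(arr / DAYS_PER_MONTH), MAX_SURVIVAL_MONTHS).astype(int)
    if np.isscalar(days) or getattr(days, "ndim", 1) == 0:
        return int(months)
    return months


def encode_year(year):
    """Code calendar year numerically: 2001 -> 0 through 2015 -> 14.

    Years back to 1991 are accepted so that lagged (pre-diagnosis) profiles can
    be encoded; codes for years before 2001 are negative.
    """
    arr = np.asarray(year, dtype=float)
    if ((arr < 1991) | (arr > YEAR_MAX)).any():
        raise ValueError(f"year out of supported range 1991-{YEAR_MAX}")
    code = (arr - YEAR_MIN).astype(int)
    if np.isscalar(year) or getattr(year, "ndim", 1) == 0:
        return int(code)
    return code
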