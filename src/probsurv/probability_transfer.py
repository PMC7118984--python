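"""Apply a survey-fitted behavior model to registry cases at pre-diagnosis lags.

For each cancer case the demographic profile is backdated by 1, 5 or 10 years
(year minus the lag; 5-year age band minus 0, 1 or 2) and pushed through the
fitted logistic model, giving the estimated probability that the case engaged
in the behavior that many years before diagnosis.  To avoid extrapolating
before the survey era, each lag restricts the eligible diagnosis years: lag 5
to 2006-2015 and lag 10 to 2011-2015.  The survey starts in 2001, so by
default lag 1 is restricted to 2002-2015; an opt-in switch admits 2001
diagnoses via extrapolation to year code -1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .behavior_model import BehaviorModelFit, build_design
from .data_prep import YEAR_MAX, YEAR_MIN

logger = logging.getLogger(__name__)

__all__ = ["LAGS", "LAG_AGE_SHIFT", "lag_profile", "lag_window", "transfer"]

LAGS = (1, 5, 10)

#: 5-year age bands to subtract for each lag (floor(lag / 5)).
LAG_AGE_SHIFT = {1: 0, 5: 1, 10: 2}

#: First eligible diagnosis year per lag under the no-extrapolation rule.
_FIRST_ELIGIBLE_YEAR = {1: 2002, 5: 2006, 10: 2011}

#: Youngest age band the survey model was fitted on (25-29); lagged profiles
#: below it are ineligible rather than clamped.
_MIN_LAGGED_AGE_BAND = 5


def _check_lag(lag_years: int) -> None:
    if lag_years not in LAGS:
        raise ValueError(f"lag_years must be one of {LAGS}, got {lag_years!r}")


def lag_profile(profiles: pd.DataFrame, lag_years: int) -> pd.DataFrame:
    """Backdate profiles: year -= lag; age band -= {0, 1, 2} for lags {1, 5, 10}.

    All other fields are unchanged.  Raises if any resulting age band would be
    negative.
    """
    _check_lag(lag_years)
    out = profiles.copy()
    out["year"] = out["year"] - lag_years
    out["age_group"] = out["age_group"] - LAG_AGE_SHIFT[lag_years]
    if (out["age_group"] < 0).any():
        raise ValueError(f"lag {lag_years} pushes an age band below 0")
    return out


def lag_window(diagnosis_year, lag_years: int, allow_2001_lag1: bool = False):
    """Whether a diagnosis year is eligible for the given lag.

    Lag 5 needs diagnoses 2006-2015 and lag 10 needs 2011-2015 (the lagged
    year must stay inside the 2001-2015 survey era).  Lag 1 needs 2002-2015
    unless ``allow_2001_lag1`` permits extrapolation to year code -1.  Accepts
    scalars or arrays.
    """
    _check_lag(lag_years)
    first = _FIRST_ELIGIBLE_YEAR[lag_years]
    if lag_years == 1 and allow_2001_lag1:
        first = YEAR_MIN
    year = np.asarray(diagnosis_year)
    eligible = (year >= first) & (year <= YEAR_MAX)
    if year.ndim == 0:
        return bool(eligible)
    return eligible


def transfer(
    fit: BehaviorModelFit,
    registry: pd.DataFrame,
    lag_years: int,
    *,
    allow_2001_lag1: bool = False,
    permissive_levels: bool = False,
) -> pd.DataFrame:
    """Estimated behavior probability for each registry case at one lag.

    Returns one row per case with columns case_id, behavior, lag_years,
    eligible, probability.  Ineligible cases (diagnosis year outside the lag's
    window, or lagged age band under 25) carry probability NaN and are meant to
    be excluded from that lag's survival model.
    """
    _check_lag(lag_years)
    if not fit.converged:
        raise RuntimeError(f"refusing to transfer from unconverged fit for {fit.behavior!r}")
    if fit.spec is None:
        raise ValueError("fit carries no DesignSpec")

    year = registry["year"].to_numpy()
    age = registry["age_group"].to_numpy()
    eligible = np.asarray(lag_window(year, lag_years, allow_2001_lag1))
    eligible = eligible & (age - LAG_AGE_SHIFT[lag_years] >= _MIN_LAGGED_AGE_BAND)

    prob = np.full(len(registry), np.nan)
    if eligible.any():
        lagged = lag_profile(registry.loc[eligible, ["year", "age_group", "sex", "race",
                                                     "marital", "state"]], lag_years)
        X = build_design(lagged, fit.spec, permissive=permissive_levels)
        prob[eligible] = fit.predict_matrix(X)

    n_inel = int((~eligible).sum())
    if n_inel:
        logger.info("transfer(%s, lag %d): %d ineligible cases", fit.behavior, lag_years, n_inel)
    return pd.DataFrame(
        {
            "case_id": registry["case_id"].to_numpy(),
            "behavior": fit.behavior,
            "lag_years": lag_years,
            "eligible": eligible,
            "probability": prob,
        }
    )
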