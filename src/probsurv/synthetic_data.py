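"""Synthetic survey/registry twin-data generator with known generative truth.

Emulates the joint structure of an annual weighted health-behavior survey and
a cancer registry that share only demographics: demographics drive behavior
through a logistic law, and demographics + (latent) behavior drive survival
through a proportional-hazards law with exponential baseline.  Because the
generative parameters are known, downstream estimates can be scored for bias,
coverage, attenuation and type-I error.

The registry's latent behavior indicators exist only for scoring; the analysis
pipeline never reads them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior_model
from .data_prep import (
    DAYS_PER_MONTH,
    MARITAL_STATUSES,
    MAX_SURVIVAL_MONTHS,
    RACES,
    RACES_WITH_MIXED,
    SEXES,
    STAGE_UNAVAILABLE,
    STAGES,
    STATES,
    YEAR_MAX,
    YEAR_MIN,
)

__all__ = [
    "ConfigurationError",
    "TruthParams",
    "BEHAVIORS",
    "HISTOLOGIES",
    "default_behavior_coefs",
    "default_demo_marginals",
    "generate_survey",
    "generate_registry",
    "generate_pair",
]

#: Behavior indicators carried by the survey (and latently by the registry).
BEHAVIORS = (
    "smoker",
    "heavy_drinking",
    "binge_drinking",
    "smoker_and_drinker",
    "obese",
    "exercise",
)

HISTOLOGIES = ("ESCC", "EAC", "other")


class ConfigurationError(ValueError):
    """Invalid generator configuration (non-summing marginals, bad rates...)."""


def default_behavior_coefs() -> dict[str, dict[str, float]]:
    """Sparse named coefficients (design scale) for each behavior.

    Slopes follow the direction and size of well-documented demographic
    gradients in US behavior surveillance: smoking declines by year and age
    and is commoner among single people, American Indian/Alaska Native
    respondents and Kentuckians; obesity rises by year and is commoner among
    Black respondents; binge drinking falls steeply with age; heavy drinking
    is rare in Utah.  Intercepts are set so marginal prevalences under the
    default demographics land near surveillance levels (smoking ~16%, heavy
    drinking ~5%, binge ~15%, concurrent smoke+drink ~5%, obesity ~27%,
    leisure exercise ~73%).  Unnamed columns are zero.
    """
    return {
        "smoker": {
            "intercept": -0.689,
            "year": math.log(0.98),
            "age_group": math.log(0.90),
            "sex[female]": math.log(0.74),
            "marital[single]": math.log(2.14),
            "marital[divorced/separated]": 0.45,
            "race[AI/AN]": math.log(1.69),
            "race[Asian/PI]": -0.55,
            "state[Kentucky]": math.log(2.50),
            "state[Utah]": -0.60,
            "age_group:sex[female]": 0.01,
            "age_group:marital[single]": -0.02,
            "sex[female]:marital[single]": 0.10,
        },
        "heavy_drinking": {
            "intercept": -2.656,
            "year": 0.005,
            "age_group": -0.03,
            "sex[female]": -0.35,
            "marital[single]": 0.40,
            "state[Utah]": math.log(0.52),
            "state[Kentucky]": -0.15,
            "sex[female]:marital[single]": 0.12,
        },
        "binge_drinking": {
            "intercept": 0.348,
            "year": -0.005,
            "age_group": math.log(0.82),
            "sex[female]": -0.80,
            "marital[single]": math.log(1.90),
            "state[Utah]": -0.70,
            "age_group:marital[single]": -0.01,
            "age_group:sex[female]": -0.02,
        },
        "smoker_and_drinker": {
            "intercept": -2.212,
            "year": -0.015,
            "age_group": -0.08,
            "sex[female]": -0.45,
            "marital[single]": math.log(2.50),
            "marital[divorced/separated]": 0.40,
            "state[Kentucky]": 0.35,
            "state[Utah]": -0.80,
        },
        "obese": {
            "intercept": -1.566,
            "year": math.log(1.03),
            "age_group": 0.035,
            "sex[female]": -0.05,
            "race[Black]": math.log(1.75),
            "race[Asian/PI]": -0.90,
            "marital[widowed]": 0.10,
            "age_group:sex[female]": 0.005,
        },
        "exercise": {
            "intercept": 1.674,
            "year": 0.005,
            "age_group": -0.065,
            "sex[female]": -0.15,
            "marital[single]": 0.10,
            "race[Black]": -0.25,
            "state[Utah]": 0.25,
        },
    }


def default_demo_marginals() -> dict[str, dict]:
    """Category probabilities for the shared demographic variables.

    ``age_survey`` spans bands 4-17 (ages 20+; the under-25 band exercises the
    survey age filter), ``age_registry`` spans bands 5-17 with 0.3% of mass
    under band 7 (under age 35, exercising the registry filter) and a bulk
    centered at ages 60-79.  Survey race includes 3.1% mixed-race respondents;
    registry race has no mixed code (mass redistributed proportionally).
    """
    return {
        "sex": {"male": 0.48, "female": 0.52},
        "race": {"White": 0.780, "Black": 0.100, "Asian/PI": 0.070, "AI/AN": 0.019, "mixed": 0.031},
        "marital": {"married": 0.55, "divorced/separated": 0.15, "widowed": 0.10, "single": 0.20},
        "state": {
            "California": 0.34, "Alaska": 0.01, "Connecticut": 0.045, "Georgia": 0.09,
            "Hawaii": 0.02, "Iowa": 0.04, "Kentucky": 0.055, "Louisiana": 0.055,
            "Michigan": 0.12, "New Jersey": 0.11, "New Mexico": 0.025, "Utah": 0.03,
            "Washington": 0.06,
        },
        "age_survey": {
            4: 0.06, 5: 0.095, 6: 0.095, 7: 0.09, 8: 0.09, 9: 0.09, 10: 0.085,
            11: 0.08, 12: 0.075, 13: 0.065, 14: 0.06, 15: 0.05, 16: 0.035, 17: 0.03,
        },
        "age_registry": {
            5: 0.0015, 6: 0.0015, 7: 0.01, 8: 0.02, 9: 0.04, 10: 0.07, 11: 0.10,
            12: 0.14, 13: 0.16, 14: 0.16, 15: 0.13, 16: 0.10, 17: 0.067,
        },
    }


@dataclass
class TruthParams:
    """Generative parameters of the synthetic world.

    ``behavior_coefs`` are named coefficients on the behavior-model design
    scale; ``log_hr_behavior`` is the true log hazard ratio per unit of the
    actual (latent) ``effect_behavior``; ``log_hr_age`` acts per 5-year age
    band; ``stage_log_hrs`` are the II/III/IV/not_specified effects versus
    stage I; ``baseline_rate`` is the exponential baseline hazard per month
    for the reference case and ``censor_rate`` the independent exponential
    censoring rate per month (0 disables random censoring; follow-up is always
    capped at 180 months).
    """

    seed: int
    n_survey: int = 50_000
    n_registry: int = 5_000
    behavior_coefs: dict[str, dict[str, float]] = field(default_factory=default_behavior_coefs)
    effect_behavior: str = "smoker"
    log_hr_behavior: float = 0.4
    log_hr_age: float = 0.03
    stage_log_hrs: tuple[float, float, float, float] = (0.35, 0.80, 1.30, 0.60)
    baseline_rate: float = 0.032
    censor_rate: float = 0.023
    demo_marginals: dict[str, dict] = field(default_factory=default_demo_marginals)
    weight_lognormal_params: tuple[float, float] = (0.0, 0.3)
    stage_probs: tuple[float, float, float, float, float] = (0.13, 0.16, 0.21, 0.32, 0.18)
    emulate_pre2004_stage_missing: bool = True
    histology_probs: tuple[float, float, float] = (0.337, 0.529, 0.134)
    informative_weights: bool = False
    informative_weight_coef: float = -0.4
    transfer_perturbation_sd: float = 0.0
    #: restrict the behavior effect to one histology (None = all cases)
    effect_histology: str | None = None

    def validate(self) -> None:
        for name in ("sex", "race", "marital", "state", "age_survey", "age_registry"):
            probs = self.demo_marginals.get(name)
            if probs is None:
                raise ConfigurationError(f"demo_marginals missing {name!r}")
            total = sum(probs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-8):
                raise ConfigurationError(f"{name} marginals sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} marginals contain negative mass")
        for probs, label in ((self.stage_probs, "stage_probs"), (self.histology_probs, "histology_probs")):
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-8):
                raise ConfigurationError(f"{label} must sum to 1")
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ConfigurationError("censor_rate must be non-negative")
        if self.n_survey < 0 or self.n_registry < 0:
            raise ConfigurationError("sample sizes must be non-negative")
        if self.effect_behavior not in self.behavior_coefs:
            raise ConfigurationError(f"effect_behavior {self.effect_behavior!r} has no coefficients")
        unknown = set(self.demo_marginals["race"]) - set(RACES_WITH_MIXED)
        if unknown:
            raise ConfigurationError(f"unknown race categories: {sorted(unknown)}")
        if self.effect_histology is not None and self.effect_histology not in HISTOLOGIES:
            raise ConfigurationError(f"unknown effect_histology {self.effect_histology!r}")

    def coef_vector(self, behavior: str, spec=behavior_model.DEFAULT_DESIGN) -> np.ndarray:
        """Dense coefficient vector in the design's column order."""
        named = self.behavior_coefs[behavior]
        cols = spec.column_names
        unknown = set(named) - set(cols)
        if unknown:
            raise ConfigurationError(
                f"behavior_coefs[{behavior!r}] names unknown design columns: {sorted(unknown)}"
            )
        return np.array([named.get(c, 0.0) for c in cols])

    def to_json(self) -> str:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, s: str) -> "TruthParams":
        d = json.loads(s)
        for k in ("stage_log_hrs", "weight_lognormal_params", "stage_probs", "histology_probs"):
            if k in d:
                d[k] = tuple(d[k])
        for age_key in ("age_survey", "age_registry"):
            if age_key in d.get("demo_marginals", {}):
                d["demo_marginals"][age_key] = {
                    int(k): v for k, v in d["demo_marginals"][age_key].items()
                }
        return cls(**d)


def _draw_categorical(rng: np.random.Generator, probs: dict, n: int) -> np.ndarray:
    labels = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return labels[rng.choice(len(labels), size=n, p=p / p.sum())]


def _draw_profiles(rng: np.random.Generator, truth: TruthParams, n: int, which: str) -> pd.DataFrame:
    m = truth.demo_marginals
    age_probs = m["age_survey"] if which == "survey" else m["age_registry"]
    race_probs = dict(m["race"])
    if which == "registry":
        race_probs.pop("mixed", None)  # the registry has no mixed-race code
    return pd.DataFrame(
        {
            "year": rng.integers(YEAR_MIN, YEAR_MAX + 1, size=n),
            "age_group": _draw_categorical(rng, age_probs, n).astype(int),
            "sex": _draw_categorical(rng, m["sex"], n),
            "race": _draw_categorical(rng, race_probs, n),
            "marital": _draw_categorical(rng, m["marital"], n),
            "state": _draw_categorical(rng, m["state"], n),
        }
    )


def _behavior_probs(
    profiles: pd.DataFrame, truth: TruthParams, perturb: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Generating inverse-logit probabilities per behavior.  Mixed-race rows use
    the reference race level (the design has no mixed column)."""
    from scipy.special import expit

    X = behavior_model.build_design(profiles, permissive=True)
    out = {}
    for b in truth.behavior_coefs:
        beta = truth.coef_vector(b)
        if perturb is not None and truth.transfer_perturbation_sd > 0:
            beta = beta + perturb.normal(0.0, truth.transfer_perturbation_sd, size=beta.shape)
        out[b] = expit(X @ beta)
    return out


def generate_survey(truth: TruthParams) -> pd.DataFrame:
    """One row per survey respondent: demographics, sampling weight, behaviors."""
    truth.validate()
    rng = np.random.default_rng([truth.seed, 1])
    n = truth.n_survey
    df = _draw_profiles(rng, truth, n, "survey")
    probs = _behavior_probs(df, truth)
    for b, p in probs.items():
        df[b] = (rng.random(n) < p).astype(int)
    mu, sigma = truth.weight_lognormal_params
    logw = rng.normal(mu, sigma, size=n)
    if truth.informative_weights and truth.effect_behavior in df.columns:
        logw = logw + truth.informative_weight_coef * df[truth.effect_behavior].to_numpy()
    df["weight"] = np.exp(logw)
    return df


def generate_registry(truth: TruthParams) -> pd.DataFrame:
    """One row per cancer case: demographics at diagnosis, histology, stage,
    discretized survival months, event flag, and latent behavior indicators.

    Latent behaviors follow the same logistic law as the survey (the
    transportability assumption); set ``transfer_perturbation_sd`` > 0 to
    deliberately violate it.  Death times are exponential with rate
    ``baseline_rate * exp(lp)`` per month where the log-hazard ``lp`` combines
    the latent effect behavior, the age band and the stage category; times are
    generated in days, censored by an independent exponential clock and the
    180-month follow-up horizon, then discretized to whole months.
    """
    truth.validate()
    rng = np.random.default_rng([truth.seed, 2])
    n = truth.n_registry
    df = _draw_profiles(rng, truth, n, "registry")
    df.insert(0, "case_id", np.arange(n))

    df["histology"] = _draw_categorical(
        rng, dict(zip(HISTOLOGIES, truth.histology_probs)), n
    )

    # stage: drawn independent of behavior; the drawn category drives the hazard
    # even when the observed label is masked (pre-2004) later.
    stage_true = _draw_categorical(rng, dict(zip(STAGES, truth.stage_probs)), n)
    stage_idx = pd.Categorical(stage_true, categories=STAGES).codes
    stage_lp = np.concatenate([[0.0], np.asarray(truth.stage_log_hrs)])[stage_idx]

    perturb = np.random.default_rng([truth.seed, 3]) if truth.transfer_perturbation_sd else None
    probs = _behavior_probs(df, truth, perturb=perturb)
    latent = {b: (rng.random(n) < p).astype(int) for b, p in probs.items()}

    behavior_x = latent[truth.effect_behavior].astype(float)
    if truth.effect_histology is not None:
        behavior_x = behavior_x * (df["histology"].to_numpy() == truth.effect_histology)
    lp = (
        truth.log_hr_behavior * behavior_x
        + truth.log_hr_age * df["age_group"].to_numpy(dtype=float)
        + stage_lp
    )
    rate_per_day = truth.baseline_rate / DAYS_PER_MONTH * np.exp(lp)
    death_days = rng.exponential(1.0, size=n) / rate_per_day
    if truth.censor_rate > 0:
        censor_days = rng.exponential(DAYS_PER_MONTH / truth.censor_rate, size=n)
    else:
        censor_days = np.full(n, np.inf)

    t_days = np.minimum(death_days, censor_days)
    months_raw = np.floor(t_days / DAYS_PER_MONTH)
    event = (death_days <= censor_days) & (months_raw <= MAX_SURVIVAL_MONTHS)
    df["survival_months"] = np.minimum(months_raw, MAX_SURVIVAL_MONTHS).astype(int)
    df["event"] = event.astype(int)

    if truth.emulate_pre2004_stage_missing:
        observed = np.where(df["year"].to_numpy() < 2004, STAGE_UNAVAILABLE, stage_true)
    else:
        observed = stage_true
    df["stage"] = observed

    for b in BEHAVIORS:
        if b in latent:
            df[f"latent_{b}"] = latent[b]
    return df


def generate_pair(truth: TruthParams) -> tuple[pd.DataFrame, pd.DataFrame, TruthParams]:
    """Generate matched survey and registry tables driven by the same behavior
    coefficients, from disjoint substreams of one seed.  Returns the truth echo
    for downstream scoring."""
    survey = generate_survey(truth)
    registry = generate_registry(truth)
    return survey, registry, replace(truth)
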