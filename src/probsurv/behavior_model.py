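"""Weighted, Firth-penalized logistic models of health behavior on demographics.

Each behavior (current smoking, heavy drinking, ...) gets its own logistic
model of the form

    logit P(behavior) = b0 + b1*year + b2*age + sex + race + marital + state
                        + age:sex + age:marital + sex:marital

with year and the 5-year age-band index entered as numeric codes, the four
categorical factors dummy-coded against fixed reference levels (male, White,
married, California), and three interaction blocks.  Fitting maximizes the
sampling-weighted Bernoulli log-likelihood plus Jeffreys-prior penalty
``l(b) + 0.5 * log det I(b)`` (Firth's bias reduction), which keeps estimates
finite under separation.  Model discrimination is summarized by the ROC AUC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .data_prep import (
    MARITAL_STATUSES,
    RACES,
    SEXES,
    STATES,
    PrepReport,
    SchemaError,
    encode_year,
    trim_extreme_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "DEFAULT_DESIGN",
    "BehaviorModelFit",
    "ROCResult",
    "build_design",
    "fit_firth_logistic",
    "fit_behavior",
    "predict_probability",
    "compute_auc",
]


@dataclass(frozen=True)
class DesignSpec:
    """Fixed encoding of a demographic profile into a model design row.

    The first level of each tuple is the reference level and gets no dummy
    column.  Column order is fixed: intercept, year code, age band, sex, race,
    marital, state dummies, then age:sex, age:marital and sex:marital
    interactions.
    """

    sex_levels: tuple[str, ...] = SEXES
    race_levels: tuple[str, ...] = RACES
    marital_levels: tuple[str, ...] = MARITAL_STATUSES
    state_levels: tuple[str, ...] = STATES

    @property
    def column_names(self) -> list[str]:
        names = ["intercept", "year", "age_group"]
        names += [f"sex[{s}]" for s in self.sex_levels[1:]]
        names += [f"race[{r}]" for r in self.race_levels[1:]]
        names += [f"marital[{m}]" for m in self.marital_levels[1:]]
        names += [f"state[{s}]" for s in self.state_levels[1:]]
        names += [f"age_group:sex[{s}]" for s in self.sex_levels[1:]]
        names += [f"age_group:marital[{m}]" for m in self.marital_levels[1:]]
        names += [
            f"sex[{s}]:marital[{m}]"
            for s in self.sex_levels[1:]
            for m in self.marital_levels[1:]
        ]
        return names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def to_dict(self) -> dict:
        return {
            "sex_levels": list(self.sex_levels),
            "race_levels": list(self.race_levels),
            "marital_levels": list(self.marital_levels),
            "state_levels": list(self.state_levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**{k: tuple(v) for k, v in d.items()})


DEFAULT_DESIGN = DesignSpec()


def _dummies(
    values: pd.Series, levels: tuple[str, ...], column: str, permissive: bool
) -> np.ndarray:
    """Dummy-code against ``levels`` (first = reference).  Unseen labels raise a
    SchemaError, or map to the reference level when ``permissive``."""
    cat = pd.Categorical(values, categories=levels)
    codes = cat.codes.copy()
    if (codes < 0).any():
        if not permissive:
            bad = values[codes < 0]
            raise SchemaError(
                f"unseen level {bad.iloc[0]!r} in column {column!r} "
                f"({int((codes < 0).sum())} rows); known levels: {list(levels)}"
            )
        logger.info(
            "build_design: %d rows with unseen %s levels mapped to reference %r",
            int((codes < 0).sum()), column, levels[0],
        )
        codes[codes < 0] = 0
    out = np.zeros((len(values), len(levels) - 1))
    for j in range(1, len(levels)):
        out[:, j - 1] = codes == j
    return out


def build_design(
    profiles: pd.DataFrame, spec: DesignSpec = DEFAULT_DESIGN, permissive: bool = False
) -> np.ndarray:
    """Expand demographic profiles into the model design matrix.

    ``profiles`` needs columns year, age_group, sex, race, marital, state.
    Returns a float array with one row per profile and ``spec.n_columns``
    columns in the documented fixed order.
    """
    required = ["year", "age_group", "sex", "race", "marital", "state"]
    missing = [c for c in required if c not in profiles.columns]
    if missing:
        raise SchemaError(f"profiles table is missing columns: {missing}")

    n = len(profiles)
    year = np.asarray(encode_year(profiles["year"].to_numpy()), dtype=float).reshape(n)
    age = profiles["age_group"].to_numpy(dtype=float)

    sex = _dummies(profiles["sex"], spec.sex_levels, "sex", permissive)
    race = _dummies(profiles["race"], spec.race_levels, "race", permissive)
    marital = _dummies(profiles["marital"], spec.marital_levels, "marital", permissive)
    state = _dummies(profiles["state"], spec.state_levels, "state", permissive)

    age_sex = age[:, None] * sex
    age_marital = age[:, None] * marital
    n_sm = sex.shape[1] * marital.shape[1]
    sex_marital = (sex[:, :, None] * marital[:, None, :]).reshape(n, n_sm)

    X = np.column_stack(
        [np.ones(n), year, age, sex, race, marital, state, age_sex, age_marital, sex_marital]
    )
    assert X.shape[1] == spec.n_columns
    return X


@dataclass
class BehaviorModelFit:
    """A fitted (optionally Firth-penalized) weighted logistic model."""

    behavior: str
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_obs: int
    penalized: bool = True
    spec: DesignSpec | None = None
    fitted_probs: np.ndarray | None = None
    weight_provenance: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Inverse-logit of the linear predictor for a pre-built design matrix."""
        return expit(self.linear_predictor(X))

    def coef_table(self) -> pd.DataFrame:
        """Named coefficients with SEs and odds ratios (the model-summary table)."""
        se = self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "odds_ratio": np.exp(self.coef),
                "or_ci_low": np.exp(self.coef - 1.959963984540054 * se),
                "or_ci_high": np.exp(self.coef + 1.959963984540054 * se),
            },
            index=self.names,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "behavior": self.behavior,
                "names": self.names,
                "coef": self.coef.tolist(),
                "cov": self.cov.tolist(),
                "loglik": self.loglik,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "n_obs": self.n_obs,
                "penalized": self.penalized,
                "spec": None if self.spec is None else self.spec.to_dict(),
                "weight_provenance": self.weight_provenance,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BehaviorModelFit":
        d = json.loads(s)
        return cls(
            behavior=d["behavior"],
            names=d["names"],
            coef=np.asarray(d["coef"]),
            cov=np.asarray(d["cov"]),
            loglik=d["loglik"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            n_obs=d["n_obs"],
            penalized=d["penalized"],
            spec=None if d["spec"] is None else DesignSpec.from_dict(d["spec"]),
            weight_provenance=d.get("weight_provenance", {}),
        )


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int


def _check_rank(X: np.ndarray, w: np.ndarray, names: list[str]) -> None:
    Xw = X * np.sqrt(w)[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # QR with pivoting: columns past the numerical rank in pivot order are
        # the ones expressible from the others.
        _, _, piv = qr(Xw, mode="economic", pivoting=True)
        collinear = [names[j] for j in sorted(piv[rank:])]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )


def _penalized_loglik(
    beta: np.ndarray, X: np.ndarray, y: np.ndarray, w: np.ndarray, penalize: bool
) -> float:
    eta = X @ beta
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    if not penalize:
        return ll
    p = expit(eta)
    W = w * p * (1.0 - p)
    sign, logdet = np.linalg.slogdet(X.T @ (X * W[:, None]))
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def fit_firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    penalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    names: list[str] | None = None,
    behavior: str = "",
    spec: DesignSpec | None = None,
) -> BehaviorModelFit:
    """Fit a weighted logistic model with Firth's Jeffreys-prior penalty.

    Maximizes ``l(b) + 0.5 log det I(b)`` where ``l`` is the weighted Bernoulli
    log-likelihood and ``I(b) = X' diag(w p (1-p)) X`` the weighted Fisher
    information.  Weights are rescaled to sum to the number of rows so the
    penalty's relative size matches the unweighted case.  Newton iterations use
    the Firth-adjusted score with step-halving on the penalized objective;
    convergence requires max |adjusted score| < ``tol``.  The returned
    covariance is the inverse information at the optimum.  With
    ``penalize=False`` this is plain weighted maximum likelihood.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")

    if weights is None:
        w = np.ones(n)
        provenance = {"weighted": False}
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        provenance = {"weighted": True, "sum_raw": float(w.sum()), "rescaled_to": n}
        w = w * (n / w.sum())

    _check_rank(X, w, names)

    beta = np.zeros(k)
    obj = _penalized_loglik(beta, X, y, w, penalize)
    converged = False
    it = 0
    info = X.T @ (X * (w * 0.25)[:, None])  # information at beta=0, updated in loop

    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        W = w * p * (1.0 - p)
        info = X.T @ (X * W[:, None])
        try:
            cho = cho_factor(info)
        except np.linalg.LinAlgError:
            converged = False
            break
        resid = w * (y - p)
        if penalize:
            A = cho_solve(cho, X.T)  # k x n
            h = W * np.einsum("ij,ji->i", X, A)
            resid = resid + h * (0.5 - p)
        score = X.T @ resid
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = cho_solve(cho, score)
        # step-halving: accept the first scale that does not decrease the objective
        scale = 1.0
        for _ in range(30):
            new_obj = _penalized_loglik(beta + scale * step, X, y, w, penalize)
            if new_obj >= obj - 1e-12:
                break
            scale *= 0.5
        else:
            converged = False
            break
        beta = beta + scale * step
        obj = new_obj
    else:
        converged = False

    if not converged:
        logger.warning("fit_firth_logistic: no convergence after %d iterations", it)

    cov = np.linalg.inv(info)
    fitted = expit(X @ beta)
    return BehaviorModelFit(
        behavior=behavior,
        names=list(names),
        coef=beta,
        cov=cov,
        loglik=obj,
        n_iter=it,
        converged=converged,
        n_obs=n,
        penalized=penalize,
        spec=spec,
        fitted_probs=fitted,
        weight_provenance=provenance,
    )


def predict_probability(
    fit: BehaviorModelFit, profiles: pd.DataFrame, permissive: bool = False
) -> np.ndarray:
    """Estimated behavior probability for each profile: expit(x b-hat)."""
    if not fit.converged:
        raise RuntimeError(f"refusing to predict from unconverged fit for {fit.behavior!r}")
    if fit.spec is None:
        raise ValueError("fit carries no DesignSpec; use predict_matrix for raw matrices")
    X = build_design(profiles, fit.spec, permissive=permissive)
    return fit.predict_matrix(X)


def compute_auc(probs, y, weights=None) -> ROCResult:
    """ROC AUC: the probability a random positive outscores a random negative
    (ties count one half).  Unweighted by default; pass ``weights`` for the
    weighted variant."""
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative case")
    auc = float(roc_auc_score(y, np.asarray(probs, dtype=float), sample_weight=weights))
    return ROCResult(auc=auc, n_pos=n_pos, n_neg=n_neg)


def fit_behavior(
    survey: pd.DataFrame,
    behavior: str,
    spec: DesignSpec = DEFAULT_DESIGN,
    *,
    trim_weights: bool = True,
    weight_col: str = "weight",
    **fit_kwargs,
) -> tuple[BehaviorModelFit, ROCResult, PrepReport]:
    """Convenience wrapper: trim extreme weights, fit one behavior, assess AUC.

    ``survey`` must already have passed eligibility filtering; weight trimming
    is applied here (once per behavior fit) on the post-eligibility table.
    """
    if behavior not in survey.columns:
        raise SchemaError(f"survey table has no behavior column {behavior!r}")
    if trim_weights:
        table, trim_report = trim_extreme_weights(survey, weight_col)
    else:
        table = survey
        trim_report = PrepReport(len(survey), len(survey), {})
    X = build_design(table, spec)
    y = table[behavior].to_numpy(dtype=float)
    w = table[weight_col].to_numpy(dtype=float)
    fit = fit_firth_logistic(
        X, y, w, names=spec.column_names, behavior=behavior, spec=spec, **fit_kwargs
    )
    roc = compute_auc(fit.fitted_probs, y)
    fit.weight_provenance["trimmed"] = trim_report.exclusions
    return fit, roc, trim_report
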