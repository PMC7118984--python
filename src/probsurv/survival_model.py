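"""Proportional-hazards models of survival months on estimated behavior probability.

The hazard model is  S(t | x) = S0(t) ^ exp(b1 * phat/0.1 + b2 * age + b3 * stage),
fitted by Newton-Raphson on the Cox partial likelihood with Efron's tie
correction (Breslow available behind a flag).  Survival is recorded in whole
months, so ties are heavy and month-0 deaths are real events: all times are
shifted by +0.5 month internally so month-0 events are orderable in risk sets
(a uniform, reversible shift that leaves risk-set membership otherwise
untouched).  The behavior-probability covariate is entered as phat / 0.1 so
its raw coefficient is directly the log hazard ratio per 0.1 increase in
probability, the unit used for reporting.  Inference is Wald throughout, with
covariance the inverse observed information at the optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_prep import STAGE_UNAVAILABLE, STAGES

logger = logging.getLogger(__name__)

__all__ = ["CoxFit", "fit_cox", "hr_per_increment", "run_models", "PROBABILITY_INCREMENT"]

#: Reporting unit for the behavior-probability covariate.
PROBABILITY_INCREMENT = 0.1

_Z975 = norm.ppf(0.975)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model."""

    names: list[str]
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int
    baseline_cumhaz: pd.DataFrame | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> pd.DataFrame:
        """Per-covariate hazard ratios with 95% Wald CIs and p-values."""
        se = self.se
        z = self.coef / se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": se,
                "hr": np.exp(self.coef),
                "hr_ci_low": np.exp(self.coef - _Z975 * se),
                "hr_ci_high": np.exp(self.coef + _Z975 * se),
                "p": 2.0 * norm.sf(np.abs(z)),
            },
            index=self.names,
        )


def _partial_loglik(beta, Xs, ts, ds, ties, want_derivs=True):
    """Log partial likelihood (and optionally gradient / negative Hessian) on
    data pre-sorted by ascending time."""
    n, p = Xs.shape
    eta = Xs @ beta
    eta = eta - eta.mean()  # exact invariance of the partial likelihood
    r = np.exp(eta)
    rx = r[:, None] * Xs
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    if want_derivs:
        rxx = rx[:, :, None] * Xs[:, None, :]
        S2 = np.cumsum(rxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    uniq, starts = np.unique(ts, return_index=True)
    bounds = np.append(starts, n)
    for k in range(len(uniq)):
        i0, i1 = bounds[k], bounds[k + 1]
        ev = ds[i0:i1]
        d = int(ev.sum())
        if d == 0:
            continue
        sl = slice(i0, i1)
        Xe = Xs[sl][ev]
        re = r[sl][ev]
        frac = np.arange(d) / d if ties == "efron" else np.zeros(d)

        D0 = re.sum()
        phi0 = S0[i0] - frac * D0
        ll += float(eta[sl][ev].sum() - np.log(phi0).sum())
        if not want_derivs:
            continue
        D1 = (re[:, None] * Xe).sum(axis=0)
        D2 = ((re[:, None] * Xe)[:, :, None] * Xe[:, None, :]).sum(axis=0)
        phi1 = S1[i0][None, :] - frac[:, None] * D1[None, :]
        phi2 = S2[i0][None, :, :] - frac[:, None, None] * D2[None, :, :]
        u1 = phi1 / phi0[:, None]
        grad += Xe.sum(axis=0) - u1.sum(axis=0)
        info += (phi2 / phi0[:, None, None]).sum(axis=0) - np.einsum("li,lj->ij", u1, u1)
    if want_derivs:
        return ll, grad, info
    return ll


def _breslow_baseline(beta, Xs, ts, ds) -> pd.DataFrame:
    """Breslow estimate of the baseline cumulative hazard at the event times."""
    r = np.exp(Xs @ beta)
    S0 = np.cumsum(r[::-1])[::-1]
    uniq, starts = np.unique(ts, return_index=True)
    bounds = np.append(starts, len(ts))
    rows = []
    cum = 0.0
    for k in range(len(uniq)):
        i0, i1 = bounds[k], bounds[k + 1]
        d = int(ds[i0:i1].sum())
        if d == 0:
            continue
        cum += d / S0[i0]
        rows.append((uniq[k], cum))
    return pd.DataFrame(rows, columns=["time", "cumulative_hazard"])


def fit_cox(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    *,
    ties: str = "efron",
    time_shift: float = 0.5,
    tol: float = 1e-7,
    max_iter: int = 50,
    compute_baseline: bool = False,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson on the partial likelihood.

    ``ties`` is "efron" (default) or "breslow".  Rows with missing values in
    any used column are excluded listwise.  ``time_shift`` (in months) is
    added uniformly to all durations so that month-0 events are orderable.
    Monotone partial likelihood (separation within risk sets) is reported as
    ``converged=False``, never silently.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    cols = [duration_col, event_col] + list(covariates)
    df = data[cols].dropna()
    n = len(df)
    if n == 0:
        raise ValueError("no complete-case rows to fit on")

    time = df[duration_col].to_numpy(dtype=float) + time_shift
    event = df[event_col].to_numpy(dtype=float).astype(bool)
    X = df[list(covariates)].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in the data")
    for j, c in enumerate(covariates):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(f"covariate {c!r} is constant; no contrast to estimate")

    order = np.argsort(time, kind="stable")
    Xs, ts, ds = X[order], time[order], event[order]

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _partial_loglik(beta, Xs, ts, ds, ties)
    converged = False
    it = 0
    grad_tol = tol * max(1.0, float(n_events))
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            new = _partial_loglik(beta + scale * step, Xs, ts, ds, ties)
            if new[0] >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = beta + scale * step
        ll, grad, info = new
        if np.max(np.abs(scale * step)) < 1e-10:  # parameter change negligible
            converged = True
            break
        if np.max(np.abs(beta)) > 100.0:  # monotone likelihood / separation
            break
    cov = np.linalg.inv(info)
    # monotone likelihood (separation in risk sets): the coefficient runs away
    # while the information collapses; never report that as a clean fit
    se = np.sqrt(np.abs(np.diag(cov)))
    if converged and np.max(np.abs(beta)) > 15.0 and np.max(se) > 100.0:
        converged = False
    if not converged:
        logger.warning("fit_cox: no convergence after %d iterations (|grad|=%.3g)",
                       it, float(np.max(np.abs(grad))))
    baseline = _breslow_baseline(beta, Xs, ts, ds) if compute_baseline else None
    return CoxFit(
        names=list(covariates),
        coef=beta,
        cov=cov,
        loglik=ll,
        n=n,
        n_events=n_events,
        ties=ties,
        converged=converged,
        n_iter=it,
        baseline_cumhaz=baseline,
    )


def hr_per_increment(fit: CoxFit, covariate: str, increment: float = PROBABILITY_INCREMENT) -> dict:
    """Hazard ratio (with 95% CI and Wald p) per ``increment`` of a covariate.

    HR = exp(increment * coef); the p-value is scale-invariant.
    """
    if covariate not in fit.names:
        raise ValueError(f"covariate {covariate!r} not in fit ({fit.names})")
    j = fit.names.index(covariate)
    b, s = fit.coef[j], fit.se[j]
    z = b / s
    return {
        "hr": float(np.exp(increment * b)),
        "ci_low": float(np.exp(increment * (b - _Z975 * s))),
        "ci_high": float(np.exp(increment * (b + _Z975 * s))),
        "p": float(2.0 * norm.sf(abs(z))),
    }


def _stage_dummies(stage: pd.Series, stage_handling: str) -> tuple[pd.DataFrame, pd.Series]:
    """Stage dummy columns (reference = stage I) and a row mask to keep.

    ``stage_handling='fold'`` merges pre-2004 unavailable stage into
    not_specified so those cases stay in adjusted fits; ``'drop'`` removes
    them from adjusted fits instead.
    """
    keep = pd.Series(True, index=stage.index)
    if stage_handling == "fold":
        stage = stage.replace(STAGE_UNAVAILABLE, "not_specified")
    elif stage_handling == "drop":
        keep = stage != STAGE_UNAVAILABLE
    else:
        raise ValueError(f"stage_handling must be 'fold' or 'drop', got {stage_handling!r}")
    dummies = pd.DataFrame(index=stage.index)
    for level in STAGES[1:]:
        col = (stage == level).astype(float)
        if col[keep].nunique() > 1:  # drop absent / constant levels
            dummies[f"stage[{level}]"] = col
    return dummies, keep


def run_models(
    exposures: pd.DataFrame,
    registry: pd.DataFrame,
    behavior: str,
    lag_years: int,
    *,
    ties: str = "efron",
    stage_handling: str = "fold",
    subgroups: tuple[str, ...] = ("all", "ESCC", "EAC"),
    adjustments: tuple[str, ...] = ("unadjusted", "adjusted"),
) -> pd.DataFrame:
    """Fit the grid of survival models for one behavior x lag.

    For each subgroup (all cases / ESCC / EAC) an unadjusted model (behavior
    probability only) and an adjusted model (probability + numeric age band +
    stage category) are fitted on lag-eligible cases, with listwise deletion
    of missing values.  Returns one row per subgroup x adjustment with the HR
    per 0.1 probability, its CI and p-value, n, events, and a note for cells
    that could not be estimated (estimation continues past them).
    """
    ex = exposures[
        (exposures["behavior"] == behavior)
        & (exposures["lag_years"] == lag_years)
        & exposures["eligible"]
    ][["case_id", "probability"]]
    merged = registry.merge(ex, on="case_id", how="inner")
    merged["prob_per_0.1"] = merged["probability"] / PROBABILITY_INCREMENT

    rows = []
    for subgroup in subgroups:
        sub = merged if subgroup == "all" else merged[merged["histology"] == subgroup]
        for adjustment in adjustments:
            rec = {
                "behavior": behavior, "lag_years": lag_years,
                "subgroup": subgroup, "adjustment": adjustment,
                "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "n": len(sub), "events": int(sub["event"].sum()) if len(sub) else 0,
                "note": "",
            }
            try:
                if adjustment == "unadjusted":
                    frame, covs = sub, ["prob_per_0.1"]
                else:
                    dummies, keep = _stage_dummies(sub["stage"], stage_handling)
                    frame = pd.concat([sub, dummies], axis=1)[keep]
                    covs = ["prob_per_0.1", "age_group"] + list(dummies.columns)
                fit = fit_cox(frame, "survival_months", "event", covs, ties=ties)
                rec["n"], rec["events"] = fit.n, fit.n_events
                if not fit.converged:
                    rec["note"] = "did not converge"
                else:
                    # covariate already scaled to per-0.1 units
                    rec.update(hr_per_increment(fit, "prob_per_0.1", increment=1.0))
            except (ValueError, np.linalg.LinAlgError) as err:
                rec["note"] = f"not estimable: {err}"
                logger.warning("run_models %s lag %d %s/%s: %s",
                               behavior, lag_years, subgroup, adjustment, err)
            rows.append(rec)
    return pd.DataFrame(rows)
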