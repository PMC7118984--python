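"""Design expansion, the weighted Firth logistic fitter, prediction and AUC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from probsurv.behavior_model import (
    DEFAULT_DESIGN,
    BehaviorModelFit,
    build_design,
    compute_auc,
    fit_firth_logistic,
    predict_probability,
)
from probsurv.behavior_model import _penalized_loglik
from probsurv.data_prep import SchemaError


def profiles_df(rows):
    return pd.DataFrame(rows, columns=["year", "age_group", "sex", "race", "marital", "state"])


REFERENCE = (2001, 0, "male", "White", "married", "California")


class TestBuildDesign:
    def test_reference_profile_is_intercept_only(self):
        X = build_design(profiles_df([REFERENCE]))
        assert X[0, 0] == 1.0
        assert np.all(X[0, 1:] == 0.0)

    def test_year_shift_changes_only_year_column(self):
        X = build_design(profiles_df([REFERENCE, (2002, 0, *REFERENCE[2:])]))
        diff = X[1] - X[0]
        year_col = DEFAULT_DESIGN.column_names.index("year")
        assert diff[year_col] == 1.0
        diff[year_col] = 0.0
        assert np.all(diff == 0.0)

    def test_hand_expanded_fixture(self):
        # three profiles expanded by hand against the documented column order
        rows = [
            (2003, 6, "female", "Black", "single", "Kentucky"),
            (2015, 10, "male", "AI/AN", "widowed", "Utah"),
            REFERENCE,
        ]
        X = build_design(profiles_df(rows))
        cols = {name: j for j, name in enumerate(DEFAULT_DESIGN.column_names)}

        row = np.zeros(DEFAULT_DESIGN.n_columns)
        row[cols["intercept"]] = 1
        row[cols["year"]] = 2
        row[cols["age_group"]] = 6
        row[cols["sex[female]"]] = 1
        row[cols["race[Black]"]] = 1
        row[cols["marital[single]"]] = 1
        row[cols["state[Kentucky]"]] = 1
        row[cols["age_group:sex[female]"]] = 6
        row[cols["age_group:marital[single]"]] = 6
        row[cols["sex[female]:marital[single]"]] = 1
        np.testing.assert_array_equal(X[0], row)

        row = np.zeros(DEFAULT_DESIGN.n_columns)
        row[cols["intercept"]] = 1
        row[cols["year"]] = 14
        row[cols["age_group"]] = 10
        row[cols["race[AI/AN]"]] = 1
        row[cols["marital[widowed]"]] = 1
        row[cols["state[Utah]"]] = 1
        row[cols["age_group:marital[widowed]"]] = 10
        np.testing.assert_array_equal(X[1], row)

        assert np.all(X[2, 1:] == 0.0)

    def test_unseen_level_raises_naming_it(self):
        bad = profiles_df([(2005, 6, "male", "White", "married", "Texas")])
        with pytest.raises(SchemaError, match="Texas"):
            build_design(bad)

    def test_permissive_maps_to_reference(self):
        bad = profiles_df([(2005, 6, "male", "White", "married", "Texas")])
        X = build_design(bad, permissive=True)
        ref = build_design(profiles_df([(2005, 6, "male", "White", "married", "California")]))
        np.testing.assert_array_equal(X, ref)


def brute_force_firth(X, y, w=None, penalize=True):
    """Independent derivative-free maximization of the penalized objective."""
    X = np.asarray(X, float)
    if w is None:
        w = np.ones(len(X))
    w = w * len(X) / w.sum()
    res = minimize(
        lambda b: -_penalized_loglik(b, X, np.asarray(y, float), w, penalize),
        np.zeros(X.shape[1]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 50_000, "maxfev": 50_000},
    )
    return res.x


class TestFirthFitter:
    def test_intercept_only_closed_form(self):
        # Jeffreys penalty adds half an event to each cell: 3 of 10 successes
        # gives expit^-1(3.5 / 11) = log(3.5 / 7.5)
        X = np.ones((10, 1))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
        fit = fit_firth_logistic(X, y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(math.log(3.5 / 7.5), abs=1e-6)

    def test_separated_data_finite(self):
        # plain ML diverges here; the Firth penalty keeps the estimate finite
        x = np.array([-1.0] * 10 + [1.0] * 10)
        X = np.column_stack([np.ones(20), x])
        y = np.array([0.0] * 10 + [1.0] * 10)
        fit = fit_firth_logistic(X, y)
        assert fit.converged
        assert np.all(np.isfinite(fit.coef))

    def test_matches_derivative_free_oracle(self, rng):
        for _ in range(5):
            n, k = int(rng.integers(20, 60)), int(rng.integers(1, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))]) if k > 1 \
                else np.ones((n, 1))
            y = (rng.random(n) < 0.4).astype(float)
            w = rng.lognormal(0, 0.4, n)
            fit = fit_firth_logistic(X, y, w)
            oracle = brute_force_firth(X, y, w)
            assert fit.converged
            np.testing.assert_allclose(fit.coef, oracle, atol=1e-4)

    def test_optimum_is_local_maximum(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < 0.3).astype(float)
        fit = fit_firth_logistic(X, y)
        w = np.ones(n)
        best = _penalized_loglik(fit.coef, X, y, w, True)
        for _ in range(20):
            probe = fit.coef + rng.normal(scale=1e-3, size=3)
            assert _penalized_loglik(probe, X, y, w, True) <= best + 1e-10

    def test_duplicated_row_equals_doubled_weight_unpenalized(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.5).astype(float)
        w = np.ones(n)
        w2 = w.copy()
        w2[0] = 2.0
        Xd = np.vstack([X, X[:1]])
        yd = np.append(y, y[0])
        fit_dup = fit_firth_logistic(Xd, yd, penalize=False)
        fit_w = fit_firth_logistic(X, y, w2, penalize=False)
        np.testing.assert_allclose(fit_dup.coef, fit_w.coef, atol=1e-8)

    def test_firth_weight_gap_shrinks_with_n(self, rng):
        def gap(n):
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = (rng.random(n) < 0.5).astype(float)
            w = np.ones(n)
            w[0] = 2.0
            dup = fit_firth_logistic(np.vstack([X, X[:1]]), np.append(y, y[0]))
            wtd = fit_firth_logistic(X, y, w)
            return np.max(np.abs(dup.coef - wtd.coef))

        assert gap(800) < gap(25)

    def test_label_flip_negates_coefficients(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_firth_logistic(X, y)
        flipped = fit_firth_logistic(X, 1.0 - y)
        np.testing.assert_allclose(fit.coef, -flipped.coef, atol=1e-6)

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_firth_logistic(X, np.array([0, 1, 0, 1, 0.0]), names=["c0", "c1", "c2"])

    def test_covariance_symmetric_psd(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_firth_logistic(X, y)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)

    def test_serialization_round_trip_predicts_identically(self, rng):
        n = 50
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_firth_logistic(X, y)
        reloaded = BehaviorModelFit.from_json(fit.to_json())
        np.testing.assert_array_equal(fit.predict_matrix(X), reloaded.predict_matrix(X))


class TestPrediction:
    def test_zero_linear_predictor_gives_half(self):
        fit = _zero_fit()
        probs = predict_probability(fit, profiles_df([REFERENCE]))
        assert probs[0] == 0.5

    def test_intercept_only_training_prediction(self):
        X = np.ones((10, 1))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], float)
        fit = fit_firth_logistic(X, y)
        np.testing.assert_allclose(fit.predict_matrix(X), 3.5 / 11, atol=1e-6)

    def test_training_predictions_reproduce_stored_fitted_values(self, rng):
        n = 40
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_firth_logistic(X, y)
        np.testing.assert_array_equal(fit.predict_matrix(X), fit.fitted_probs)

    def test_unconverged_fit_refused(self):
        fit = _zero_fit()
        fit.converged = False
        with pytest.raises(RuntimeError, match="unconverged"):
            predict_probability(fit, profiles_df([REFERENCE]))


def _zero_fit():
    k = DEFAULT_DESIGN.n_columns
    return BehaviorModelFit(
        behavior="smoker", names=DEFAULT_DESIGN.column_names, coef=np.zeros(k),
        cov=np.eye(k), loglik=0.0, n_iter=0, converged=True, n_obs=0,
        spec=DEFAULT_DESIGN,
    )


def brute_force_auc(scores, y):
    scores, y = np.asarray(scores, float), np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for s in pos:
        for t in neg:
            total += 1.0 if s > t else (0.5 if s == t else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0

    def test_all_tied_scores(self):
        assert compute_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]).auc == 0.5

    def test_enumerated_example(self):
        # pairs: (0.35 vs 0.1 ok), (0.35 vs 0.4 bad), (0.8 vs both ok) -> 3/4
        assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]).auc == 0.75

    def test_matches_pairwise_concordance(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            res = compute_auc(scores, y)
            assert res.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_label_flip_complements(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        scores = rng.random(50)
        a = compute_auc(scores, y).auc
        b = compute_auc(scores, 1 - y).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.2, 0.4], [1, 1])
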