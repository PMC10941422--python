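"""Stacking ensemble, correlation diagnostic, grid search, bias/variance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.base import clone

from dbpstack.features_sequence import EncoderSpec, encode_records
from dbpstack.stacking import (StackModelSpec, StackedClassifier,
                               bias_variance_estimate, correlation_matrix,
                               fit_stack, grid_search_svc, load_model,
                               save_model)
from dbpstack.stacking import _base_estimators


@pytest.fixture(scope="module")
def xy(small_benchmark):
    records, y = small_benchmark
    X = encode_records(records, [EncoderSpec("AAC"), EncoderSpec("GAAC")])
    return X, y


@pytest.fixture(scope="module")
def fitted(xy):
    X, y = xy
    return fit_stack(X, y, StackModelSpec(seed=0))


class TestCorrelationMatrix:
    def test_identical_vectors_r_one(self, rng):
        v = rng.random(30)
        M = correlation_matrix({"a": v, "b": v.copy()}).matrix
        assert M.loc["a", "b"] == pytest.approx(1.0)

    def test_complement_vectors_r_minus_one(self, rng):
        v = rng.random(30)
        M = correlation_matrix({"a": v, "b": 1 - v}).matrix
        assert M.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        vs = {f"m{i}": rng.random(50) for i in range(3)}
        M = correlation_matrix(vs).matrix
        for a in vs:
            for b in vs:
                va, vb = vs[a], vs[b]
                r = (np.mean((va - va.mean()) * (vb - vb.mean()))
                     / (va.std() * vb.std()))
                assert M.loc[a, b] == pytest.approx(r)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        vs = {f"m{i}": rng.random(40) for i in range(4)}
        M = correlation_matrix(vs).matrix
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert (M.abs().to_numpy() <= 1 + 1e-12).all()

    def test_zero_variance_vector_excluded_from_selection(self, rng):
        vs = {"flat": np.full(30, 0.5), "a": rng.random(30),
              "b": rng.random(30), "c": rng.random(30)}
        cm = correlation_matrix(vs)
        assert "flat" in cm.undefined
        assert np.isnan(cm.matrix.loc["flat", "a"])
        assert "flat" not in cm.least_correlated(2)

    def test_least_correlated_selection(self):
        t = np.linspace(0, 1, 40)
        vs = {"x": t, "x2": t + 0.01 * np.sin(t * 9),
              "anti": 1 - t + 0.01 * np.cos(t * 7)}
        cm = correlation_matrix(vs)
        assert "anti" in cm.least_correlated(1)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_matrix({"a": rng.random(5), "b": rng.random(6)})


class TestStackFit:
    def test_separable_benchmark_cv_accuracy(self, xy):
        from dbpstack.evaluation import cross_validate
        X, y = xy
        report, _ = cross_validate(X, y, StackModelSpec(seed=0),
                                   scheme=("kfold", 5), seed=0)
        assert report.ACC >= 0.95

    def test_probabilities_bounded_and_threshold_consistent(self, fitted, xy):
        X, _ = xy
        p = fitted.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()
        assert np.array_equal(fitted.predict(X), (p >= 0.5).astype(int))

    def test_training_points_of_separable_set_predicted_correctly(self, fitted, xy):
        X, y = xy
        assert (fitted.predict(X) == y).mean() >= 0.98

    def test_column_permutation_invariance(self, fitted, xy):
        X, _ = xy
        shuffled = X[list(X.columns[::-1])]
        assert np.array_equal(fitted.predict_proba(X),
                              fitted.predict_proba(shuffled))

    def test_feature_name_mismatch_rejected(self, fitted, xy):
        X, _ = xy
        with pytest.raises(ValueError, match="feature-name mismatch"):
            fitted.predict_proba(X.iloc[:, :5])

    def test_empty_voting_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty voting"):
            StackModelSpec(voting_members=())

    def test_single_class_rejected(self, xy):
        X, _ = xy
        with pytest.raises(ValueError, match="both classes"):
            fit_stack(X, np.ones(len(X), dtype=int))

    def test_nan_features_rejected(self, xy):
        X, y = xy
        bad = X.copy()
        bad.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_stack(bad, y)

    def test_fixed_seed_bit_identical_predictions(self, xy):
        X, y = xy
        a = fit_stack(X, y, StackModelSpec(seed=5)).predict_proba(X)
        b = fit_stack(X, y, StackModelSpec(seed=5)).predict_proba(X)
        assert np.array_equal(a, b)

    def test_duplicated_columns_keep_decisions_stable(self, xy):
        # regression check: duplicating every feature column leaves the
        # ensemble's decisions on a separable problem unchanged
        X, y = xy
        dup = pd.concat(
            [X, X.add_suffix("_copy")], axis=1)
        a = fit_stack(X, y, StackModelSpec(seed=1)).predict(X)
        b = fit_stack(dup, y, StackModelSpec(seed=1)).predict(dup)
        assert (a == b).mean() >= 0.98


class TestMetaLeakageGuard:
    def test_meta_features_come_from_held_out_folds(self, xy):
        """Recompute fold-wise base predictions; each sample's meta-feature
        must equal the prediction of models trained without it."""
        X, y = xy
        spec = StackModelSpec(seed=3, inner_cv_folds=4)
        model = fit_stack(X, y, spec)
        Xs = model.scaler_.transform(X[model.feature_names_].to_numpy())
        skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=3)
        for fi, (tr, te) in enumerate(skf.split(Xs, y)):
            assert (model.meta_fold_assignment_[te] == fi).all()
            pairs = [(n, clone(e).fit(Xs[tr], np.asarray(y)[tr]))
                     for n, e in _base_estimators(spec)]
            Z = np.column_stack([est.predict_proba(Xs[te])[:, 1]
                                 for _, est in pairs])
            assert np.allclose(model.meta_features_[te], Z)

    def test_fold_assignment_is_a_partition(self, fitted, xy):
        X, _ = xy
        folds = fitted.meta_fold_assignment_
        assert folds.min() >= 0
        assert len(folds) == len(X)


class TestGridSearch:
    def test_singleton_grid_forced(self, xy):
        X, y = xy
        C, g, table = grid_search_svc(X, y, [5.445], [0.00237], folds=3,
                                      seed=0)
        assert (C, g) == (5.445, 0.00237)
        assert len(table) == 1

    def test_two_by_two_grid_matches_brute_force(self, xy):
        from sklearn.model_selection import cross_val_score
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        X, y = xy
        C_grid, g_grid = [0.1, 10.0], [0.01, 1.0]
        C, g, table = grid_search_svc(X, y, C_grid, g_grid, folds=3, seed=1)
        cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=1)
        best = max(
            ((c_, g_) for c_ in C_grid for g_ in g_grid),
            key=lambda cg: (cross_val_score(
                Pipeline([("s", StandardScaler()),
                          ("m", SVC(C=cg[0], gamma=cg[1], random_state=1))]),
                X.to_numpy(), y, cv=cv).mean(), -cg[0], -cg[1]))
        assert (C, g) == best

    def test_empty_grid_rejected(self, xy):
        X, y = xy
        with pytest.raises(ValueError, match="empty"):
            grid_search_svc(X, y, [], [0.1])


class TestBiasVariance:
    def test_constant_predictor_has_zero_variance(self, xy):
        X, y = xy
        const = DummyClassifier(strategy="constant", constant=1)
        bias, var = bias_variance_estimate(X, y, const, n_rounds=5, seed=0)
        assert var == 0.0
        # always-positive predictor: bias = negative fraction of the test side
        assert bias == pytest.approx(0.5, abs=0.05)

    def test_decomposition_identity(self, xy):
        X, y = xy
        spec = StackModelSpec(seed=0, inner_cv_folds=3)
        bias, var = bias_variance_estimate(X, y, spec, n_rounds=3, seed=0)
        # exact MSE decomposition: bias + variance equals the average MSE
        assert bias >= 0 and var >= 0
        assert bias + var <= 1.0 + 1e-9

    def test_seeded_repeatability(self, xy):
        X, y = xy
        const = DummyClassifier(strategy="most_frequent")
        a = bias_variance_estimate(X, y, const, n_rounds=4, seed=7)
        b = bias_variance_estimate(X, y, const, n_rounds=4, seed=7)
        assert a == b

    def test_too_few_rounds_rejected(self, xy):
        X, y = xy
        with pytest.raises(ValueError, match="n_rounds"):
            bias_variance_estimate(X, y, StackModelSpec(), n_rounds=1)


class TestSerialization:
    def test_round_trip_predictions_identical(self, tmp_path, fitted, xy):
        X, _ = xy
        path = tmp_path / "model.joblib"
        save_model(fitted, path)
        back = load_model(path)
        assert np.array_equal(back.predict_proba(X), fitted.predict_proba(X))

    def test_unfitted_model_cannot_be_saved(self, tmp_path):
        with pytest.raises(RuntimeError, match="not fitted"):
            save_model(StackedClassifier(StackModelSpec()), tmp_path / "m")
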