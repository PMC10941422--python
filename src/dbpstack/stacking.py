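"""Two-layer stacking ensemble for DNA-binding-protein classification.

Base layer: (i) a soft-voting ensemble of a decision tree, adaptive boosting
and linear discriminant analysis — the three least mutually correlated of the
candidate classifiers — and (ii) an RBF-kernel support-vector classifier with
grid-searched (C, gamma), probability-calibrated.  Meta layer: logistic
regression on the base models' held-out positive-class probabilities,
generated by inner stratified cross-validation so no base model contributes a
meta-feature for a sample it trained on.

Also here: the Pearson-correlation base-selection diagnostic, the SVC
hyperparameter grid search, and a bootstrap MSE bias/variance decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, VotingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["StackModelSpec", "StackedClassifier", "CorrelationMatrix",
           "correlation_matrix", "fit_stack", "grid_search_svc",
           "bias_variance_estimate", "save_model", "load_model"]

SERIALIZATION_VERSION = 1

#: Grid-searched RBF-SVC hyperparameters used as the packaged defaults.
DEFAULT_SVC_C = 5.445
DEFAULT_SVC_GAMMA = 0.00237


@dataclass(frozen=True)
class StackModelSpec:
    """Frozen description of the stacking architecture."""

    svc_C: float = DEFAULT_SVC_C
    svc_gamma: float = DEFAULT_SVC_GAMMA
    voting_members: tuple = ("decision_tree", "adaboost", "lda")
    voting_mode: str = "soft"
    meta: str = "logistic_regression"
    meta_input: str = "probabilities"
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.svc_C <= 0 or self.svc_gamma <= 0:
            raise ValueError("svc_C and svc_gamma must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")
        if not self.voting_members:
            raise ValueError("empty voting ensemble")
        if self.voting_mode not in ("soft", "hard"):
            raise ValueError("voting_mode must be 'soft' or 'hard'")
        if self.meta_input not in ("probabilities", "labels"):
            raise ValueError("meta_input must be 'probabilities' or 'labels'")


def _member(name: str, seed: int):
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown voting member {name!r}")


def _base_estimators(spec: StackModelSpec):
    vc = VotingClassifier(
        estimators=[(m, _member(m, spec.seed)) for m in spec.voting_members],
        voting=spec.voting_mode,
    )
    # Platt-calibrated RBF SVC (sigmoid calibration on internal CV folds)
    svc = CalibratedClassifierCV(
        SVC(C=spec.svc_C, gamma=spec.svc_gamma, kernel="rbf",
            random_state=spec.seed),
        method="sigmoid", ensemble=False)
    return [("voting", vc), ("svc", svc)]


class StackedClassifier:
    """Fitted stacking ensemble; operates on named feature matrices.

    Features are z-score standardized with statistics from the training data
    only.  Prediction aligns columns by name, so column-permuted input gives
    identical output.  Fixed seed => bit-identical fitted predictions.
    """

    def __init__(self, spec: StackModelSpec):
        self.spec = spec
        self.feature_names_ = None
        self.scaler_ = None
        self.base_ = None
        self.meta_ = None
        self.meta_features_ = None
        self.meta_fold_assignment_ = None

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _as_frame(X):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with named columns")
        return X

    def _base_outputs(self, fitted_pairs, Xs):
        cols = []
        for name, est in fitted_pairs:
            if self.spec.meta_input == "labels" or (
                    name == "voting" and self.spec.voting_mode == "hard"):
                cols.append(est.predict(Xs).astype(float))
            else:
                cols.append(est.predict_proba(Xs)[:, 1])
        return np.column_stack(cols)

    # -- API ----------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y):
        X = self._as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("y must contain both classes")
        values = X.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("features must be finite (no NaN/inf)")
        self.feature_names_ = list(X.columns)
        self.scaler_ = StandardScaler().fit(values)
        Xs = self.scaler_.transform(values)

        # Inner-CV meta-features: each sample's meta-feature comes from base
        # models that never saw it during their inner-fold training.
        skf = StratifiedKFold(n_splits=self.spec.inner_cv_folds, shuffle=True,
                              random_state=self.spec.seed)
        Z = np.zeros((len(y), 2))
        fold_of = np.full(len(y), -1, dtype=int)
        for fi, (tr, te) in enumerate(skf.split(Xs, y)):
            pairs = [(n, clone(e).fit(Xs[tr], y[tr]))
                     for n, e in _base_estimators(self.spec)]
            Z[te] = self._base_outputs(pairs, Xs[te])
            fold_of[te] = fi
        self.meta_features_ = Z
        self.meta_fold_assignment_ = fold_of

        self.meta_ = LogisticRegression(random_state=self.spec.seed).fit(Z, y)
        # refit base layer on the full training set for prediction time
        self.base_ = [(n, clone(e).fit(Xs, y))
                      for n, e in _base_estimators(self.spec)]
        return self

    def _check_fitted(self):
        if self.base_ is None:
            raise RuntimeError("model is not fitted")

    def _transform(self, X):
        X = self._as_frame(X)
        missing = set(self.feature_names_) - set(X.columns)
        if missing:
            raise ValueError(
                f"feature-name mismatch: {len(missing)} training features "
                f"absent (e.g. {sorted(missing)[:3]})"
            )
        return self.scaler_.transform(
            X[self.feature_names_].to_numpy(dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        """Positive-class probability per sample, in [0, 1]."""
        self._check_fitted()
        Z = self._base_outputs(self.base_, self._transform(X))
        return self.meta_.predict_proba(Z)[:, 1]

    def predict(self, X) -> np.ndarray:
        """Label = positive-class probability >= 0.5."""
        return (self.predict_proba(X) >= 0.5).astype(int)


def fit_stack(X: pd.DataFrame, y, spec: StackModelSpec | None = None) -> StackedClassifier:
    """Fit the stacking ensemble on a named feature matrix."""
    return StackedClassifier(spec or StackModelSpec()).fit(X, y)


# ---------------------------------------------------------------------------
# base-selection diagnostic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlation of classifiers' held-out probabilities."""

    matrix: pd.DataFrame
    undefined: tuple = ()

    def least_correlated(self, m: int) -> list:
        """The m classifiers with minimal mean off-diagonal correlation,
        excluding any with undefined (zero-variance) predictions."""
        names = [n for n in self.matrix.index if n not in self.undefined]
        sub = self.matrix.loc[names, names]
        k = len(names)
        if m > k:
            raise ValueError(f"asked for {m} of {k} defined classifiers")
        mean_off = (sub.sum(axis=1) - 1.0) / (k - 1) if k > 1 else sub.sum(axis=1)
        return list(mean_off.sort_values(kind="stable").index[:m])


def correlation_matrix(prob_vectors: dict) -> CorrelationMatrix:
    """Pairwise Pearson r of predicted positive-class probabilities.

    Zero-variance vectors get NaN rows/columns and are excluded from
    ``least_correlated`` selection.
    """
    names = list(prob_vectors)
    arrs = {n: np.asarray(v, dtype=float) for n, v in prob_vectors.items()}
    lengths = {a.shape[0] for a in arrs.values()}
    if len(lengths) != 1 or min(lengths) < 2:
        raise ValueError("all probability vectors must share a length >= 2")
    undefined = tuple(n for n, a in arrs.items() if a.std() == 0)
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if a in undefined or b in undefined:
                r = np.nan
            else:
                r = float(pearsonr(arrs[a], arrs[b]).statistic)
            M.loc[a, b] = M.loc[b, a] = r
        if a in undefined:
            M.loc[a, a] = np.nan
    return CorrelationMatrix(M, undefined)


# ---------------------------------------------------------------------------
# SVC grid search
# ---------------------------------------------------------------------------

def grid_search_svc(X, y, C_grid, gamma_grid, folds: int = 10, seed: int = 0):
    """Exhaustive (C, gamma) grid search for the RBF SVC by mean stratified-CV
    accuracy; ties prefer smaller C, then smaller gamma.

    Returns ``(best_C, best_gamma, cv_table)``.
    """
    C_grid = list(C_grid)
    gamma_grid = list(gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rows = []
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            pipe = Pipeline([
                ("scale", StandardScaler()),
                ("svc", SVC(C=C, gamma=gamma, kernel="rbf",
                            random_state=seed)),
            ])
            scores = cross_val_score(pipe, Xv, y, cv=cv, scoring="accuracy")
            rows.append({"C": C, "gamma": gamma,
                         "mean_score": float(scores.mean()),
                         "sd_score": float(scores.std())})
    table = pd.DataFrame(rows)
    best = table.sort_values(["mean_score", "C", "gamma"],
                             ascending=[False, True, True],
                             kind="stable").iloc[0]
    return float(best["C"]), float(best["gamma"]), table


# ---------------------------------------------------------------------------
# bias / variance
# ---------------------------------------------------------------------------

def bias_variance_estimate(X: pd.DataFrame, y, model, n_rounds: int = 20,
                           seed: int = 0, test_size: float = 0.3):
    """Bootstrap MSE bias/variance decomposition over a held-out split.

    ``model`` is a StackModelSpec (the stacking ensemble is refit per round)
    or any scikit-learn classifier (cloned per round).  The training set is
    bootstrap-resampled ``n_rounds`` times; each refit model predicts labels
    on the fixed test split.  With the mean prediction as the main
    prediction, per test point
    ``mean((pred - y)^2) = (main - y)^2 + var(pred)`` exactly, so the
    returned (avg_bias, avg_variance) sum to the average MSE.
    """
    if n_rounds < 2:
        raise ValueError("n_rounds must be >= 2")
    y = np.asarray(y)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=y)
    if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
        raise ValueError("degenerate split: a side lacks a class")
    rng = np.random.default_rng(seed)
    preds = np.zeros((n_rounds, len(te)))
    for r in range(n_rounds):
        boot = rng.choice(tr, size=len(tr), replace=True)
        if isinstance(model, StackModelSpec):
            fitted = StackedClassifier(replace(model, seed=model.seed + r)).fit(
                X.iloc[boot], y[boot])
            preds[r] = fitted.predict(X.iloc[te])
        else:
            fitted = clone(model).fit(X.iloc[boot].to_numpy(dtype=float),
                                      y[boot])
            preds[r] = fitted.predict(X.iloc[te].to_numpy(dtype=float))
    main = preds.mean(axis=0)
    avg_bias = float(np.mean((main - y[te]) ** 2))
    avg_var = float(np.mean(preds.var(axis=0)))
    return avg_bias, avg_var


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: StackedClassifier, path) -> None:
    """Single versioned archive: spec, feature names, scaler statistics and
    all fitted learners."""
    model._check_fitted()
    joblib.dump({"version": SERIALIZATION_VERSION, "model": model}, path)


def load_model(path) -> StackedClassifier:
    payload = joblib.load(path)
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(
            f"unsupported model archive version {payload.get('version')!r}")
    return payload["model"]
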