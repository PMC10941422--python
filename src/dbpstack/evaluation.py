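"""Evaluation metrics, cross-validation schemes and comparison statistics.

Threshold metrics (accuracy, sensitivity, specificity, precision, F1,
Matthews correlation) are computed exactly from confusion counts; ranking
metrics (AUROC by the trapezoidal rule, AUPR as non-interpolated
precision-recall area) from scores.  Cross-validation pools held-out
predictions (micro-averaged metrics), which makes the jackknife — one
prediction per fold — well-defined.  Classifier comparison uses the Friedman
rank test with the chi-squared reference distribution and Holm step-down
adjustment of the pairwise rank-difference z-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .stacking import StackedClassifier, StackModelSpec

__all__ = ["ConfusionCounts", "MetricsReport", "FriedmanResult",
           "metrics_from_counts", "curve_metrics", "cross_validate",
           "bootstrap_replicates", "imbalanced_subsample", "friedman_holm"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.TN + self.FP + self.FN == 0:
            raise ValueError("all confusion counts are zero")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    SN: float
    SP: float
    PREC: float
    F1: float
    MCC: float
    AUROC: float = float("nan")
    AUPR: float = float("nan")
    zero_denominator_flags: tuple = ()

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("ACC", "SN", "SP", "PREC", "F1", "MCC",
                          "AUROC", "AUPR")}


def _ratio(num, den, name, flags):
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """Exact threshold metrics from confusion counts.

    Any metric with a zero denominator is reported as 0 and its name is
    recorded in ``zero_denominator_flags``.
    """
    flags: list = []
    total = c.TP + c.TN + c.FP + c.FN
    acc = (c.TP + c.TN) / total
    sn = _ratio(c.TP, c.TP + c.FN, "SN", flags)
    sp = _ratio(c.TN, c.TN + c.FP, "SP", flags)
    prec = _ratio(c.TP, c.TP + c.FP, "PREC", flags)
    f1 = _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, "F1", flags)
    mcc_den = np.sqrt(float(c.TP + c.FP) * (c.TP + c.FN)
                      * (c.TN + c.FP) * (c.TN + c.FN))
    mcc = _ratio(c.TP * c.TN - c.FP * c.FN, mcc_den, "MCC", flags)
    return MetricsReport(ACC=acc, SN=sn, SP=sp, PREC=prec, F1=f1, MCC=mcc,
                         zero_denominator_flags=tuple(flags))


def curve_metrics(y_true, y_score) -> tuple:
    """(AUROC, AUPR) from continuous scores.

    AUROC is the trapezoidal ROC area (equals the tie-aware normalized
    Mann-Whitney U); AUPR the step-wise non-interpolated precision-recall
    area.  Both classes must be present.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if not np.isfinite(y_score).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present")
    return (float(roc_auc_score(y_true, y_score)),
            float(average_precision_score(y_true, y_score)))


def _fold_iter(scheme, y, seed):
    if scheme == "jackknife":
        return LeaveOneOut().split(np.zeros_like(y), y)
    kind, k = scheme
    if kind != "kfold":
        raise ValueError(f"unknown scheme {scheme!r}")
    if k > len(y):
        raise ValueError("k exceeds the sample count")
    if k == len(y):
        return LeaveOneOut().split(np.zeros_like(y), y)
    return StratifiedKFold(n_splits=k, shuffle=True,
                           random_state=seed).split(np.zeros_like(y), y)


def cross_validate(X: pd.DataFrame, y, model, scheme=("kfold", 10),
                   seed: int = 0):
    """Pooled cross-validated evaluation.

    ``model`` is a StackModelSpec (a stacking ensemble is fitted per fold) or
    any scikit-learn classifier with predict_proba (cloned per fold).
    ``scheme`` is ``("kfold", k)`` (stratified; k = n falls back to
    leave-one-out) or ``"jackknife"``.  Held-out probabilities are pooled
    over all folds before computing metrics, so the jackknife — a single
    prediction per fold — is handled identically.

    Returns ``(MetricsReport, fold_table)``.
    """
    y = np.asarray(y)
    proba = np.full(len(y), np.nan)
    rows = []
    for fi, (tr, te) in enumerate(_fold_iter(scheme, y, seed)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fi}: training side lacks a class")
        if isinstance(model, StackModelSpec):
            fitted = StackedClassifier(model).fit(X.iloc[tr], y[tr])
            p = fitted.predict_proba(X.iloc[te])
        else:
            est = clone(model)
            fitted = est.fit(X.iloc[tr].to_numpy(dtype=float), y[tr])
            p = fitted.predict_proba(X.iloc[te].to_numpy(dtype=float))[:, 1]
        proba[te] = p
        rows.append({"fold": fi, "n_test": len(te),
                     "acc": float(np.mean((p >= 0.5).astype(int) == y[te]))})
    counts = ConfusionCounts.from_labels(y, (proba >= 0.5).astype(int))
    rep = metrics_from_counts(counts)
    auroc, aupr = curve_metrics(y, proba)
    rep = MetricsReport(**{**rep.as_dict(), "AUROC": auroc, "AUPR": aupr},
                        zero_denominator_flags=rep.zero_denominator_flags)
    return rep, pd.DataFrame(rows)


def bootstrap_replicates(labels, n_reps: int = 20, seed: int = 0) -> list:
    """Class-stratified bootstrap index sets.

    Each replicate samples every class with replacement back to its original
    size, so class proportions are preserved exactly.  Replicate r uses seed
    ``seed + r``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if any(np.sum(labels == c) == 0 for c in classes) or len(classes) == 0:
        raise ValueError("empty class")
    reps = []
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        parts = [rng.choice(np.flatnonzero(labels == c),
                            size=int(np.sum(labels == c)), replace=True)
                 for c in classes]
        reps.append(np.sort(np.concatenate(parts)))
    return reps


def imbalanced_subsample(labels, target_prevalence: float,
                         seed: int = 0) -> np.ndarray:
    """Indices keeping all negatives and a positive subset (sampled without
    replacement) whose prevalence is the closest achievable to the target.

    E.g. 178 negatives at target 0.063 keeps 12 positives (12/190 = 6.3%).
    At the 0.5 boundary with equal classes, everything is kept.
    """
    if not 0.0 < target_prevalence <= 0.5:
        raise ValueError("target_prevalence must lie in (0, 0.5]")
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    best_p = min(
        range(1, len(pos) + 1),
        key=lambda p: (abs(p / (p + len(neg)) - target_prevalence), p),
    )
    if best_p / (best_p + len(neg)) < target_prevalence and best_p == len(pos):
        warnings.warn("insufficient positives to reach the target prevalence")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pos, size=best_p, replace=False)
    return np.sort(np.concatenate([chosen, neg]))


@dataclass(frozen=True)
class FriedmanResult:
    avg_ranks: pd.Series
    statistic: float
    df: int
    critical_value: float
    p_value: float
    reject_null: bool
    alpha: float
    holm_adjusted_p: pd.Series

    def __str__(self):
        verdict = "rejected" if self.reject_null else "retained"
        return (f"Friedman chi2({self.df}) = {self.statistic:.4f} "
                f"(critical {self.critical_value:.2f} at alpha={self.alpha}); "
                f"null {verdict}")


def friedman_holm(accuracy_table: pd.DataFrame, alpha: float = 0.05) -> FriedmanResult:
    """Friedman rank test across datasets + Holm-adjusted pairwise z-tests.

    ``accuracy_table`` has methods as rows and datasets as columns (higher is
    better; rank 1 = best, ties share average ranks).  The tie-corrected
    Friedman statistic is referred to the chi-squared distribution with
    ``n_methods - 1`` degrees of freedom and compared against the critical
    value at ``alpha``.  Pairwise p-values use the rank-difference z statistic
    with SE = sqrt(k(k+1) / (6N)) and Holm step-down adjustment.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    A = accuracy_table.astype(float)
    if A.isna().any().any():
        raise ValueError("accuracy table contains NaN cells")
    k, N = A.shape
    if k < 2 or N < 2:
        raise ValueError("need >= 2 methods and >= 2 datasets")
    # per-dataset ranks: best (highest accuracy) gets rank 1; ties averaged
    ranks = A.rank(axis=0, ascending=False, method="average")
    avg_ranks = ranks.mean(axis=1)
    R = ranks.sum(axis=1).to_numpy()
    # tie-corrected chi-squared statistic (reduces to the classic
    # 12/(Nk(k+1)) * sum R^2 - 3N(k+1) form without ties)
    A2 = float((ranks.to_numpy() ** 2).sum())
    C = N * k * (k + 1) ** 2 / 4.0
    denom = A2 - C
    if denom == 0:
        statistic = 0.0
    else:
        statistic = (k - 1) * float(((R - N * (k + 1) / 2.0) ** 2).sum()) / denom
    df = k - 1
    critical = float(stats.chi2.ppf(1 - alpha, df))
    p_value = float(stats.chi2.sf(statistic, df))

    se = np.sqrt(k * (k + 1) / (6.0 * N))
    pairs, raw = [], []
    methods = list(A.index)
    for i in range(k):
        for j in range(i + 1, k):
            z = (avg_ranks.iloc[i] - avg_ranks.iloc[j]) / se
            pairs.append(f"{methods[i]} vs {methods[j]}")
            raw.append(2 * stats.norm.sf(abs(z)))
    order = np.argsort(raw, kind="stable")
    m = len(raw)
    adj = np.empty(m)
    running = 0.0
    for rank_pos, oi in enumerate(order):
        running = max(running, (m - rank_pos) * raw[oi])
        adj[oi] = min(1.0, running)
    return FriedmanResult(
        avg_ranks=avg_ranks,
        statistic=float(statistic),
        df=df,
        critical_value=critical,
        p_value=p_value,
        reject_null=bool(statistic > critical),
        alpha=alpha,
        holm_adjusted_p=pd.Series(adj, index=pairs),
    )
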