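"""Staged recursive feature elimination with cross-validation (RFECV).

A coarse-to-fine schedule: each stage runs recursive elimination with a fixed
step (features dropped per iteration, importance from a seeded random forest
refit on the surviving set), scoring each subset size by stratified K-fold
accuracy.  The next stage restarts from the previous stage's best size plus
one step of margin (carryover), with a strictly smaller step, ending at
single-feature elimination.  Ties in the CV curve prefer the smaller subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

__all__ = ["SelectionSchedule", "SelectionResult", "run_rfecv_stage",
           "run_staged_selection", "default_schedule"]


@dataclass(frozen=True)
class SelectionSchedule:
    """Ordered elimination stages with strictly decreasing steps.

    Each stage dict has ``input_top_k`` (int or "all") and ``step``.  The
    benchmark-scale default mirrors the published schedule
    (1000 -> 100 -> 25 -> 1 with carryover = previous step).
    """

    stages: tuple
    cv_folds: int = 10
    scoring: str = "accuracy"
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        steps = [s["step"] for s in self.stages]
        if not steps:
            raise ValueError("schedule needs at least one stage")
        if any(b >= a for a, b in zip(steps, steps[1:])):
            raise ValueError("steps must be strictly decreasing across stages")


def default_schedule(seed: int = 0, cv_folds: int = 10) -> SelectionSchedule:
    """The published coarse-to-fine schedule for a full-scale feature bank."""
    return SelectionSchedule(
        stages=(
            {"input_top_k": "all", "step": 1000},
            {"input_top_k": "carryover", "step": 100},
            {"input_top_k": "carryover", "step": 25},
            {"input_top_k": "carryover", "step": 1},
        ),
        cv_folds=cv_folds,
        seed=seed,
    )


@dataclass
class SelectionResult:
    ranked_features: list          # best first
    best_subset: list
    cv_curves: list                # one DataFrame per stage
    n_selected: int
    stage_best_sizes: list = field(default_factory=list)


def _forest(seed, n_estimators):
    return RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1)


def run_rfecv_stage(X: pd.DataFrame, y, step: int, cv_folds: int = 10,
                    seed: int = 0, n_estimators: int = 100):
    """One recursive-elimination stage.

    Returns ``(best_k, cv_curve, ranking)``: the subset size with maximal
    mean stratified-CV accuracy (ties -> smaller), the size/score curve, and
    the full feature ranking (best first; elimination order reversed, the
    final survivors ordered by their last importances).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    if step < 1:
        raise ValueError("step must be >= 1")
    if X.shape[1] < 1:
        raise ValueError("X has no features")
    if step >= X.shape[1]:
        raise ValueError(
            f"step {step} must be smaller than the feature count {X.shape[1]}")
    current = list(X.columns)
    eliminated = []  # worst dropped first overall
    curve_rows = []
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    while True:
        Xc = X[current].to_numpy()
        scores = cross_val_score(_forest(seed, n_estimators), Xc, y, cv=cv,
                                 scoring="accuracy")
        curve_rows.append({"n_features": len(current),
                           "mean_score": float(scores.mean()),
                           "sd_score": float(scores.std())})
        fitted = _forest(seed, n_estimators).fit(Xc, y)
        importances = fitted.feature_importances_
        order = np.lexsort((np.arange(len(current)), importances))
        if len(current) <= step:
            # final survivors ranked by importance, best first
            survivors = [current[i] for i in order[::-1]]
            ranking = survivors + eliminated[::-1]
            break
        drop_idx = set(order[:step].tolist())
        # worst-first within this elimination round
        eliminated.extend(current[i] for i in order[:step])
        current = [f for i, f in enumerate(current) if i not in drop_idx]
    curve = pd.DataFrame(curve_rows)
    best_row = curve.sort_values(["mean_score", "n_features"],
                                 ascending=[False, True]).iloc[0]
    best_k = int(best_row["n_features"])
    return best_k, curve, ranking


def run_staged_selection(X: pd.DataFrame, y,
                         schedule: SelectionSchedule,
                         n_estimators: int = 100) -> SelectionResult:
    """Run the full coarse-to-fine schedule.

    Stage s+1 receives the top ``best_k_s + step_s`` features of stage s
    (carryover margin = previous stage's step), so e.g. a best size of 6856
    under step 1000 hands 7856 features to the next stage.
    """
    features = list(X.columns)
    curves = []
    stage_best = []
    ranking = features
    best_k = len(features)
    for si, stage in enumerate(schedule.stages):
        top_k = stage.get("input_top_k", "carryover")
        if isinstance(top_k, int):
            features = ranking[:top_k]
        elif si > 0:
            carry = min(len(ranking),
                        stage_best[-1] + schedule.stages[si - 1]["step"])
            features = ranking[:carry]
        # else "all" / "carryover" on the first stage: keep everything
        best_k, curve, ranking = run_rfecv_stage(
            X[features], y, step=stage["step"], cv_folds=schedule.cv_folds,
            seed=schedule.seed, n_estimators=n_estimators)
        curves.append(curve)
        stage_best.append(best_k)
    return SelectionResult(
        ranked_features=ranking,
        best_subset=ranking[:best_k],
        cv_curves=curves,
        n_selected=best_k,
        stage_best_sizes=stage_best,
    )


def carryover_size(best_k: int, step: int) -> int:
    """Number of features handed to the next stage: best size + one step."""
    return best_k + step


def write_selection(result: SelectionResult, features_path, curve_path) -> None:
    """Serialize the selected feature names and the per-stage CV curves."""
    with open(features_path, "w") as fh:
        for name in result.best_subset:
            fh.write(name + "\n")
    rows = []
    for si, curve in enumerate(result.cv_curves):
        c = curve.copy()
        c.insert(0, "stage", si + 1)
        rows.append(c)
    pd.concat(rows, ignore_index=True).to_csv(curve_path, sep="\t", index=False)
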