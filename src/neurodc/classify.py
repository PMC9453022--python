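"""Classifier training and evaluation: LOOCV, ROC/AUC, kappa, permutations.

Three classifiers — linear-kernel SVM, random forest, and logistic
regression — are evaluated with leave-one-out cross-validation: each
subject is predicted by a model trained on all the others, with
training-only standardisation and an inner stratified grid search for
hyperparameters.  A single ROC curve is pooled from all held-out
decision scores; its AUC equals the normalised Mann-Whitney U statistic
of the scores.  Significance is assessed by a permutation test that
shuffles the labels and re-runs the whole LOOCV (optionally re-running
feature selection per permutation), with the add-one p-value rule.

The positive class is MCI throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import itertools

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "ModelSpec",
    "ModelReport",
    "DEFAULT_GRIDS",
    "loocv_predict",
    "compute_metrics",
    "cohen_kappa",
    "permutation_test",
    "feature_weights",
    "fit_full_model",
    "run_all_models",
]

MODEL_NAMES = ("svm_linear", "random_forest", "logistic_regression")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm_linear": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "random_forest": {
        "n_estimators": [100, 500],
        "max_depth": [None, 3, 5],
    },
}


@dataclass
class ModelSpec:
    """One classifier plus its hyperparameter grid and seed."""

    model: str = "svm_linear"
    hyperparameter_grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.model not in MODEL_NAMES:
            raise ValueError(f"model must be one of {MODEL_NAMES}, got {self.model!r}")
        if not self.hyperparameter_grid:
            self.hyperparameter_grid = {
                k: list(v) for k, v in DEFAULT_GRIDS[self.model].items()
            }
        if any(len(v) == 0 for v in self.hyperparameter_grid.values()):
            raise ValueError("hyperparameter grid entries must be nonempty")

    @property
    def n_grid_points(self) -> int:
        n = 1
        for v in self.hyperparameter_grid.values():
            n *= len(v)
        return n


@dataclass
class ModelReport:
    """LOOCV evaluation summary for one classifier."""

    model: str
    confusion: tuple[int, int, int, int]  # TP, FN, FP, TN (MCI positive)
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    kappa: float
    permutation_p: float | None = None
    n_permutations: int = 0
    chosen_hyperparameters: dict = field(default_factory=dict)
    feature_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        tp, fn, fp, tn = self.confusion
        n = tp + fn + fp + tn
        assert abs(self.accuracy - (tp + tn) / n) < 1e-12
        assert abs(self.sensitivity - tp / (tp + fn)) < 1e-12
        assert abs(self.specificity - tn / (tn + fp)) < 1e-12

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _base_estimator(spec: ModelSpec, params: dict):
    if spec.model == "svm_linear":
        return SVC(kernel="linear", random_state=spec.seed, **params)
    if spec.model == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **params)
    return LogisticRegression(max_iter=2000, random_state=spec.seed, **params)


class _Fitted:
    """A standardiser + estimator fitted together on one training set."""

    def __init__(self, mu: np.ndarray, sd: np.ndarray, model):
        self.mu, self.sd, self.model = mu, sd, model

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu) / self.sd


def _fit_one(spec: ModelSpec, params: dict, x: np.ndarray, y: np.ndarray) -> _Fitted:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    model = _base_estimator(spec, params)
    model.fit((x - mu) / sd, y)
    return _Fitted(mu, sd, model)


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _fit_with_search(spec: ModelSpec, x: np.ndarray, y: np.ndarray):
    """Fit scaler+model on (x, y) with an inner stratified grid search.

    Accuracy-scored stratified ``inner_folds``-fold search; ties keep
    the earliest grid combination.
    """
    combos = _grid_combinations(spec.hyperparameter_grid)
    if len(combos) == 1:
        return _fit_one(spec, combos[0], x, y), combos[0]
    inner = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=spec.seed)
    folds = list(inner.split(x, y))
    scores = np.zeros(len(combos))
    for k, params in enumerate(combos):
        correct = 0
        for train_idx, test_idx in folds:
            fitted = _fit_one(spec, params, x[train_idx], y[train_idx])
            pred = fitted.model.predict(fitted.transform(x[test_idx]))
            correct += int(np.sum(pred == y[test_idx]))
        scores[k] = correct
    best = combos[int(np.argmax(scores))]
    return _fit_one(spec, best, x, y), best


def _score(spec: ModelSpec, fitted: _Fitted, x: np.ndarray) -> np.ndarray:
    """Continuous decision score: signed margin (SVM) or P(class 1)."""
    xs = fitted.transform(x)
    if spec.model == "svm_linear":
        return fitted.model.decision_function(xs)
    return fitted.model.predict_proba(xs)[:, 1]


def loocv_predict(
    spec: ModelSpec, matrix: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out (hard label, continuous score) for every subject.

    Subject i is predicted by a model fitted — including its inner
    hyperparameter search and standardisation — on the other n-1
    subjects only.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 subjects for LOOCV")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    hard = np.empty(n, dtype=int)
    score = np.empty(n, dtype=float)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        y_tr = labels[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"training set single-class when holding out subject {i}")
        fitted, _ = _fit_with_search(spec, matrix[train], y_tr)
        score[i] = _score(spec, fitted, matrix[i : i + 1])[0]
        if spec.model == "svm_linear":
            hard[i] = int(score[i] > 0)
        else:
            hard[i] = int(score[i] > 0.5)
    return hard, score


def pooled_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC of the pooled held-out scores (ties count one half)."""
    return float(roc_auc_score(labels, scores))


def cohen_kappa(confusion: tuple[int, int, int, int]) -> float:
    """Chance-corrected agreement from a (TP, FN, FP, TN) confusion.

    kappa = (p_o - p_e) / (1 - p_e); if p_e = 1 (degenerate marginals)
    kappa is defined as 0 by convention.
    """
    tp, fn, fp, tn = confusion
    n = tp + fn + fp + tn
    if n <= 0:
        raise ValueError("empty confusion table")
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if p_e >= 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def compute_metrics(
    labels: np.ndarray,
    hard: np.ndarray,
    scores: np.ndarray,
    model: str = "svm_linear",
) -> ModelReport:
    """Confusion counts, accuracy/sensitivity/specificity, AUC and kappa."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("true labels contain a single class")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    tp = int(np.sum((labels == 1) & (hard == 1)))
    fn = int(np.sum((labels == 1) & (hard == 0)))
    fp = int(np.sum((labels == 0) & (hard == 1)))
    tn = int(np.sum((labels == 0) & (hard == 0)))
    n = len(labels)
    return ModelReport(
        model=model,
        confusion=(tp, fn, fp, tn),
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=pooled_auc(labels, scores),
        kappa=cohen_kappa((tp, fn, fp, tn)),
    )


def permutation_test(
    spec: ModelSpec,
    matrix: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    statistic: str = "auc",
    selection: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> tuple[float, dict]:
    """Permutation p-value for the pooled-LOOCV statistic.

    ``selection``, if given, maps (matrix, labels) to a column-index
    array and is re-run for every permutation (nested selection), so the
    null distribution reflects the whole pipeline.  With no selected
    columns the model degenerates to a constant score (AUC 0.5).
    p = (1 + #{perm stat >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0x9E12,)))

    def _stat(y: np.ndarray) -> float:
        if selection is not None:
            cols = selection(matrix, y)
            if len(cols) == 0:
                return 0.5 if statistic == "auc" else max(np.mean(y), 1 - np.mean(y))
            x = matrix[:, cols]
        else:
            x = matrix
        hard, score = loocv_predict(spec, x, y)
        if statistic == "auc":
            return pooled_auc(y, score)
        if statistic == "accuracy":
            return float(np.mean(hard == y))
        raise ValueError(f"unknown statistic {statistic!r}")

    observed = _stat(labels)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        null[b] = _stat(rng.permutation(labels))
    p = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    summary = {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if n_permutations > 1 else 0.0,
        "null_q95": float(np.quantile(null, 0.95)),
        "statistic": statistic,
    }
    return p, summary


def fit_full_model(spec: ModelSpec, matrix: np.ndarray, labels: np.ndarray):
    """Fit on the full cohort (with inner search) for weight reporting."""
    return _fit_with_search(spec, np.asarray(matrix, dtype=float), np.asarray(labels))


def feature_weights(spec: ModelSpec, fitted, feature_names: list[str]) -> dict[str, float]:
    """Per-feature contribution of a fitted model.

    Linear SVM and logistic regression expose signed coefficients on the
    standardised features; random forest exposes impurity importances
    (nonnegative, summing to 1).
    """
    model = fitted.model if isinstance(fitted, _Fitted) else fitted
    if spec.model in ("svm_linear", "logistic_regression"):
        if getattr(model, "kernel", "linear") != "linear":
            raise ValueError("coefficients are only defined for a linear kernel")
        w = np.ravel(model.coef_)
    else:
        w = np.asarray(model.feature_importances_)
    return {name: float(wk) for name, wk in zip(feature_names, w)}


def run_all_models(
    table_matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_permutations: int = 0,
    grids: dict[str, dict[str, list]] | None = None,
    statistic: str = "auc",
    selection: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    return_scores: bool = False,
):
    """Evaluate SVM, RF and LR under identical folds and seeds.

    Returns per-model reports and a 3 x 5 comparison table (AUC,
    Accuracy, Sensitivity, Specificity, Kappa); with
    ``return_scores=True`` also the per-model held-out scores.
    """
    reports: dict[str, ModelReport] = {}
    held_out: dict[str, np.ndarray] = {}
    for name in MODEL_NAMES:
        grid = (grids or {}).get(name, {})
        spec = ModelSpec(model=name, hyperparameter_grid=dict(grid), seed=seed)
        hard, score = loocv_predict(spec, table_matrix, labels)
        held_out[name] = score
        report = compute_metrics(labels, hard, score, model=name)
        fitted, chosen = fit_full_model(spec, table_matrix, labels)
        report.chosen_hyperparameters = {
            k.replace("model__", ""): v for k, v in chosen.items()
        }
        report.feature_weights = feature_weights(spec, fitted, feature_names)
        if n_permutations > 0:
            p, _ = permutation_test(
                spec,
                table_matrix,
                labels,
                n_permutations=n_permutations,
                seed=seed,
                statistic=statistic,
                selection=selection,
            )
            report.permutation_p = p
            report.n_permutations = n_permutations
        reports[name] = report
    rows = {
        "SVM": reports["svm_linear"],
        "RF": reports["random_forest"],
        "LR": reports["logistic_regression"],
    }
    comparison = pd.DataFrame(
        {
            "AUC": [r.auc for r in rows.values()],
            "Accuracy": [r.accuracy for r in rows.values()],
            "Sensitivity": [r.sensitivity for r in rows.values()],
            "Specificity": [r.specificity for r in rows.values()],
            "Kappa": [r.kappa for r in rows.values()],
        },
        index=list(rows),
    )
    if return_scores:
        return reports, comparison, held_out
    return reports, comparison


def roc_coordinates(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """Pooled ROC curve coordinates (FPR, TPR, threshold)."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
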