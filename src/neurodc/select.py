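"""Two-stage feature selection: correlation pruning then L1 selection.

Stage 1 iteratively removes one member of the most-correlated feature
pair until no retained pair exceeds the absolute-correlation threshold
(0.75 by default); the member removed is the one with the larger mean
absolute correlation against the other retained features.

Stage 2 fits an L1-penalised logistic model over a log-uniform penalty
grid (10^-6 .. 10^3 in steps of 10^0.2, 46 values) with stratified
k-fold cross-validation, scores each penalty by the mean squared error
between the predicted class-1 probability and the 0/1 label, refits at
the best penalty, and keeps the features with nonzero coefficients.
Features are z-standardised (training folds only, inside CV) so the
penalty is scale-equitable.  A plain linear-lasso-on-0/1-labels mode is
available via ``mode="linear"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SelectionResult",
    "correlation_prune",
    "make_alpha_grid",
    "lasso_select",
    "select_features",
]

NONZERO_TOL = 1e-8


@dataclass
class SelectionResult:
    """Outcome of pruning + cross-validated L1 selection."""

    kept_after_prune: list[str]
    alpha_grid: list[float]
    cv_mse_per_alpha: list[float]
    best_alpha: float
    nonzero_features: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        if self.best_alpha not in self.alpha_grid:
            raise ValueError("best_alpha must be a grid point")
        if not np.all(np.isfinite(self.cv_mse_per_alpha)):
            raise ValueError("cv MSE values must be finite")
        stray = set(self.nonzero_features) - set(self.kept_after_prune)
        if stray:
            raise ValueError(f"selected features {sorted(stray)} were pruned earlier")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "SelectionResult":
        return cls(**json.loads(Path(path).read_text()))


def correlation_prune(
    matrix: np.ndarray,
    feature_names: list[str],
    threshold: float = 0.75,
    iterative: bool = True,
) -> list[str]:
    """Drop redundant features until no pair's |r| exceeds ``threshold``.

    At each step the currently most-correlated retained pair is found
    and the member with the larger mean absolute correlation over all
    other retained features is removed (ties: the earlier column).  The
    single-pass variant (``iterative=False``) walks pairs once in
    descending |r| without recomputing means.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if p < 2:
        raise ValueError("need at least 2 features to prune")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    sd = matrix.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant feature column {feature_names[flat[0]]!r}")
    corr = np.abs(np.corrcoef(matrix, rowvar=False))
    np.fill_diagonal(corr, 0.0)

    retained = list(range(p))

    def _mean_abs(i: int, pool: list[int]) -> float:
        others = [j for j in pool if j != i]
        return float(corr[i, others].mean()) if others else 0.0

    if iterative:
        while len(retained) > 1:
            sub = corr[np.ix_(retained, retained)]
            flat_idx = int(np.argmax(sub))
            a, b = divmod(flat_idx, len(retained))
            if sub[a, b] <= threshold:
                break
            i, j = retained[a], retained[b]
            i, j = min(i, j), max(i, j)
            drop = i if _mean_abs(i, retained) >= _mean_abs(j, retained) else j
            retained.remove(drop)
    else:
        pairs = [
            (corr[i, j], i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if corr[i, j] > threshold
        ]
        removed: set[int] = set()
        for _, i, j in sorted(pairs, key=lambda t: -t[0]):
            if i in removed or j in removed:
                continue
            pool = [k for k in range(p) if k not in removed]
            drop = i if _mean_abs(i, pool) >= _mean_abs(j, pool) else j
            removed.add(drop)
        retained = [k for k in range(p) if k not in removed]
    return [feature_names[k] for k in retained]


def make_alpha_grid() -> np.ndarray:
    """Log-uniform penalty grid 10^-6 .. 10^3 in steps of 10^0.2 (46 points)."""
    return np.logspace(-6.0, 3.0, 46)


def _l1_logistic(alpha: float, n_train: int, seed: int) -> LogisticRegression:
    # per-sample-mean loss convention: C = 1 / (n * alpha)
    return LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (n_train * alpha),
        solver="liblinear",
        max_iter=1000,
        random_state=seed,
    )


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    if other is None:
        return (train - mu) / sd
    return (train - mu) / sd, (other - mu) / sd


def lasso_select(
    matrix: np.ndarray,
    labels: np.ndarray,
    feature_names: list[str],
    alpha_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    mode: str = "logistic",
) -> SelectionResult:
    """Cross-validated L1 selection on (already pruned) features.

    ``labels`` are 0/1 with 1 = MCI.  The CV criterion for each penalty
    is the pooled MSE between held-out predicted probabilities (or raw
    linear predictions in ``mode="linear"``) and the labels; ties on the
    criterion go to the larger penalty (the sparser model).
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if matrix.shape[1] == 0:
        raise ValueError("empty feature set")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class count ({counts.min()})"
        )
    if alpha_grid is None:
        alpha_grid = make_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(matrix, labels))
    cv_mse = np.empty(len(alpha_grid))
    for k, alpha in enumerate(alpha_grid):
        sq_err, n_pred = 0.0, 0
        for train_idx, test_idx in folds:
            x_tr, x_te = _standardize(matrix[train_idx], matrix[test_idx])
            y_tr = labels[train_idx]
            if mode == "logistic":
                model = _l1_logistic(alpha, len(train_idx), seed)
                model.fit(x_tr, y_tr)
                pred = model.predict_proba(x_te)[:, 1]
            elif mode == "linear":
                model = Lasso(alpha=alpha, max_iter=10000)
                model.fit(x_tr, y_tr)
                pred = model.predict(x_te)
            else:
                raise ValueError(f"unknown mode {mode!r}")
            sq_err += float(np.sum((pred - labels[test_idx]) ** 2))
            n_pred += len(test_idx)
        cv_mse[k] = sq_err / n_pred

    best_mse = cv_mse.min()
    best_idx = int(np.flatnonzero(cv_mse == best_mse)[-1])  # ties -> larger alpha
    best_alpha = float(alpha_grid[best_idx])

    x_all = _standardize(matrix)
    if mode == "logistic":
        final = _l1_logistic(best_alpha, len(labels), seed)
    else:
        final = Lasso(alpha=best_alpha, max_iter=10000)
    final.fit(x_all, labels)
    coefs = np.ravel(final.coef_)
    nonzero = {
        feature_names[k]: float(coefs[k])
        for k in range(len(feature_names))
        if abs(coefs[k]) > NONZERO_TOL
    }
    return SelectionResult(
        kept_after_prune=list(feature_names),
        alpha_grid=[float(a) for a in alpha_grid],
        cv_mse_per_alpha=[float(m) for m in cv_mse],
        best_alpha=best_alpha,
        nonzero_features=nonzero,
        seed=seed,
    )


def select_features(
    table,
    threshold: float = 0.75,
    n_folds: int = 10,
    seed: int = 0,
    alpha_grid: np.ndarray | None = None,
    mode: str = "logistic",
    iterative_prune: bool = True,
) -> SelectionResult:
    """Prune then LASSO-select on a :class:`neurodc.features.FeatureTable`."""
    kept = correlation_prune(
        table.matrix, table.region_names, threshold=threshold, iterative=iterative_prune
    )
    pruned = table.select_columns(kept)
    return lasso_select(
        pruned.matrix,
        table.y,
        kept,
        alpha_grid=alpha_grid,
        n_folds=n_folds,
        seed=seed,
        mode=mode,
    )
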