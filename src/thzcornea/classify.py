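"""Endothelium-integrity classification from spectral-slope predictors.

Samples are labelled intact when their endothelial cell density exceeds
3000 cells/mm^2 (strictly).  A linear support vector machine is trained
and evaluated over repeated randomized 70/30 train/test splits (Monte
Carlo cross-validation, the operational reading of a small-sample
"bootstrapping" protocol): in each iteration the margin penalty C is
grid-searched by stratified k-fold cross-validation on the training
split scored by accuracy, predictors are z-scored with training-split
statistics, and the test-split ROC is computed from the decision
function.  ROC curves are vertically averaged on a fixed 101-point FPR
grid and the AUC is reported as mean +/- standard deviation over
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ECD_INTACT_THRESHOLD",
    "PREDICTOR_COLUMNS",
    "SampleLabel",
    "EvaluationConfig",
    "ClassifierResult",
    "CorrelationReport",
    "label_from_ecd",
    "evaluate_predictor_set",
    "correlation_report",
]

#: Cell-density threshold (cells/mm^2); strictly above is "intact".
ECD_INTACT_THRESHOLD = 3000.0

#: Canonical predictor names and their feature-table columns.
PREDICTOR_COLUMNS = {
    "S_Start": "S_Start_ps",
    "S_Elev": "S_Elev_ps",
    "S_Phys": "S_Phys_ps",
}


def label_from_ecd(ecd: float) -> str:
    """'intact' iff ECD > 3000 cells/mm^2 (strict), else 'damaged'."""
    if ecd <= 0:
        raise ValueError(f"ECD must be > 0, got {ecd}")
    return "intact" if ecd > ECD_INTACT_THRESHOLD else "damaged"


@dataclass
class SampleLabel:
    sample_id: str
    ecd: float
    label: str = ""

    def __post_init__(self) -> None:
        derived = label_from_ecd(self.ecd)
        if self.label and self.label != derived:
            raise ValueError(f"label {self.label!r} inconsistent with ECD {self.ecd}")
        self.label = derived


@dataclass(frozen=True)
class EvaluationConfig:
    """Settings of the repeated-split SVM evaluation."""

    n_iterations: int = 300
    train_fraction: float = 0.7
    kernel: str = "linear"
    c_grid: Sequence[float] = field(
        default_factory=lambda: tuple(10.0 ** np.arange(-3, 4))
    )
    cv_folds: int = 5
    stratify: bool = True
    max_redraws: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")
        if len(self.c_grid) == 0 or min(self.c_grid) <= 0:
            raise ValueError("C grid must be non-empty and positive")


@dataclass
class ClassifierResult:
    """Averaged outcome of one predictor set over all iterations."""

    predictor_set: str
    aucs: np.ndarray
    fpr_grid: np.ndarray
    tpr_mean: np.ndarray
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        self.aucs = np.asarray(self.aucs, float)
        if len(self.aucs) != self.n_iterations:
            raise ValueError("one AUC per iteration required")
        if np.any(self.aucs < 0) or np.any(self.aucs > 1):
            raise ValueError("AUC values must lie in [0, 1]")
        if np.any(np.diff(self.tpr_mean) < -1e-12):
            raise ValueError("mean ROC must be monotone nondecreasing")

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_std(self) -> float:
        return float(np.std(self.aucs))

    def to_dict(self) -> dict:
        return {
            "predictor_set": self.predictor_set,
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "roc": {
                "fpr": self.fpr_grid.tolist(),
                "tpr_mean": self.tpr_mean.tolist(),
            },
        }


def _auc_from_scores(y_true: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC of continuous scores against boolean labels.

    Satisfies the label-flip identity auc(~y, s) = 1 - auc(y, s) for
    tie-free scores.
    """
    return float(roc_auc_score(y_true.astype(int), scores))


def _stratified_split(y: np.ndarray, test_fraction: float, seed_key: tuple):
    """Class-stratified index split, invariant under relabelling.

    Each class's RNG is keyed by its smallest member index rather than
    its name, so flipping every label yields the identical partition.
    """
    test_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        rng = np.random.default_rng(np.random.SeedSequence(seed_key + (int(members[0]),)))
        perm = rng.permutation(members)
        n_test = int(round(test_fraction * len(members)))
        n_test = min(max(n_test, 1), len(members) - 1)
        test_idx.extend(perm[:n_test])
    test = np.sort(np.asarray(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def _plain_split(y: np.ndarray, test_fraction: float, seed_key: tuple, max_redraws: int):
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))
    n = len(y)
    n_test = min(max(int(round(test_fraction * n)), 1), n - 1)
    for _ in range(max_redraws):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if len(np.unique(y[test])) == 2 and len(np.unique(y[train])) == 2:
            return np.sort(train), np.sort(test)
    raise RuntimeError(
        f"could not draw a two-class test split in {max_redraws} attempts"
    )


def _grid_search_c(x_train, y_train, config: EvaluationConfig, rng: np.random.Generator) -> float:
    """Best margin penalty by k-fold CV accuracy on the training split.

    Folds are stratified by class (round-robin after a shuffle); ties
    prefer the smallest C.
    """
    classes, counts = np.unique(y_train, return_counts=True)
    k = int(min(config.cv_folds, counts.min()))
    if k < 2:
        return float(config.c_grid[0])
    fold = np.empty(len(y_train), dtype=int)
    for cls in classes:
        members = rng.permutation(np.flatnonzero(y_train == cls))
        fold[members] = np.arange(len(members)) % k
    best_c, best_acc = float(config.c_grid[0]), -1.0
    for c in config.c_grid:
        preds = np.empty(len(y_train), dtype=int)
        for j in range(k):
            tr, va = fold != j, fold == j
            clf = SVC(kernel=config.kernel, C=float(c))
            clf.fit(x_train[tr], y_train[tr])
            preds[va] = clf.predict(x_train[va])
        acc = accuracy_score(y_train, preds)
        if acc > best_acc + 1e-12:
            best_acc, best_c = acc, float(c)
    return best_c


def evaluate_predictor_set(
    features: pd.DataFrame,
    predictors: Sequence[str],
    config: EvaluationConfig = EvaluationConfig(),
    labels: Optional[pd.DataFrame] = None,
    fpr_grid_points: int = 101,
) -> ClassifierResult:
    """Repeated-split linear-SVM evaluation of one predictor set.

    ``features`` must contain the predictor columns plus either an
    ``ecd_cells_per_mm2`` column or be joinable with ``labels`` on
    ``sample_id``.  Returns per-iteration AUCs and the vertically
    averaged ROC curve.
    """
    if len(predictors) == 0:
        raise ValueError("predictor set must be non-empty")
    unknown = [p for p in predictors if p not in PREDICTOR_COLUMNS]
    if unknown:
        raise ValueError(f"unknown predictors {unknown}; choose from {list(PREDICTOR_COLUMNS)}")
    df = features
    if "ecd_cells_per_mm2" not in df.columns:
        if labels is None:
            raise ValueError("need ecd_cells_per_mm2 in features or a labels table")
        df = df.merge(labels[["sample_id", "ecd_cells_per_mm2"]], on="sample_id", how="inner")

    ordered = [p for p in PREDICTOR_COLUMNS if p in predictors]
    x = df[[PREDICTOR_COLUMNS[p] for p in ordered]].to_numpy(float)
    y = (df["ecd_cells_per_mm2"].to_numpy(float) > ECD_INTACT_THRESHOLD).astype(int)
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("need at least 2 samples per class")

    fpr_grid = np.linspace(0.0, 1.0, fpr_grid_points)
    aucs = np.empty(config.n_iterations)
    tpr_sum = np.zeros_like(fpr_grid)
    test_fraction = 1.0 - config.train_fraction
    for i in range(config.n_iterations):
        if config.stratify:
            train, test = _stratified_split(y, test_fraction, (config.seed, i))
        else:
            train, test = _plain_split(y, test_fraction, (config.seed, i), config.max_redraws)
        scaler = StandardScaler().fit(x[train])
        x_tr, x_te = scaler.transform(x[train]), scaler.transform(x[test])
        cv_rng = np.random.default_rng(np.random.SeedSequence((config.seed, i, 10**6)))
        c = _grid_search_c(x_tr, y[train], config, cv_rng)
        clf = SVC(kernel=config.kernel, C=c)
        clf.fit(x_tr, y[train])
        scores = clf.decision_function(x_te)
        aucs[i] = _auc_from_scores(y[test].astype(bool), scores)
        fpr, tpr, _ = roc_curve(y[test], scores)
        tpr_sum += np.interp(fpr_grid, fpr, tpr)
    tpr_mean = tpr_sum / config.n_iterations
    tpr_mean[0] = 0.0
    tpr_mean[-1] = 1.0
    return ClassifierResult(
        predictor_set="+".join(ordered),
        aucs=aucs,
        fpr_grid=fpr_grid,
        tpr_mean=tpr_mean,
        n_iterations=config.n_iterations,
        seed=config.seed,
    )


@dataclass(frozen=True)
class CorrelationReport:
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlation_report(features: pd.DataFrame) -> CorrelationReport:
    """OLS fit of S_Phys on S_Elev with its coefficient of determination.

    The post-elevation slope is causally downstream of the elevated-IOP
    slope (irreversible damage persists), so a strong linear relation is
    the expected signature of the damaged class.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 samples")
    x = features["S_Elev_ps"].to_numpy(float)
    y = features["S_Phys_ps"].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise ValueError("zero variance in S_Elev")
    fit = stats.linregress(x, y)
    return CorrelationReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(features),
    )
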