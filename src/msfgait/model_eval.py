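"""SVM classification under LOOCV, metric suite, forward selection, ranking.

The positive class is 'autism' throughout.  Leave-one-out cross-validation
fits one model per held-out sample, z-scoring features with the training
fold's statistics; held-out predictions are pooled into a single confusion
matrix (per-fold metrics are meaningless for single-sample folds) and
decision scores are retained for ROC/AUC.

Metric conventions: any 0/0 ratio is reported as 0 — this matches the
degenerate all-negative classifier, whose PPV, F1 and MCC are all zero.
MCC uses the standard product-of-marginals denominator.

Model comparison uses summed ranking: each metric is midranked across models
(1 = best), ranks are summed (SR) and the lowest SR wins; SR ties resolve by
higher accuracy, then model name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import POSITIVE_LABEL
from .errors import InputError
from .features import FeatureTable

DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID: tuple = ("scale", 0.001, 0.01, 0.1, 1.0)


# --------------------------------------------------------------------------
# Confusion-derived metrics
# --------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Binary confusion counts with 'autism' as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _ratio(num: float, den: float) -> float:
    """Safe ratio with the 0/0 -> 0 convention."""
    return 0.0 if den == 0 else num / den


@dataclass
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    mcc: float
    auc: float | None = None

    def as_dict(self, with_auc: bool = True) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        if with_auc and self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Full metric suite from one confusion matrix (AUC left unset)."""
    if counts.total == 0:
        raise InputError("empty confusion matrix")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricSet(
        accuracy=(tp + tn) / counts.total,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        mcc=_ratio(tp * tn - fp * fn, denom),
    )


# --------------------------------------------------------------------------
# Models and LOOCV
# --------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """An SVM configuration over a named feature subset."""

    kernel: str = "rbf"                      # 'linear' | 'rbf'
    C: float = 1.0
    gamma: float | str = "scale"
    features: list[str] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise InputError(f"unsupported kernel: {self.kernel!r}")
        if self.C <= 0:
            raise InputError("C must be positive")


def _encode(labels: pd.Series) -> np.ndarray:
    """autism -> 1 (positive), control -> 0."""
    return (labels == POSITIVE_LABEL).to_numpy(int)


def _fit_svm(X: np.ndarray, y: np.ndarray, spec: ModelSpec) -> tuple:
    scaler = StandardScaler().fit(X)
    clf = SVC(kernel=spec.kernel, C=spec.C, gamma=spec.gamma)
    clf.fit(scaler.transform(X), y)
    return scaler, clf


def loocv_evaluate(
    table: FeatureTable, spec: ModelSpec
) -> tuple[MetricSet, np.ndarray, ConfusionCounts]:
    """LOOCV: metrics from pooled held-out predictions + decision scores.

    Returns (metrics-with-AUC, per-sample decision scores, confusion counts).
    Raises if any training fold would be single-class.
    """
    feats = spec.features or table.feature_names
    X = table.data[feats].to_numpy(float)
    y = _encode(table.labels)
    n = len(y)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise InputError("need at least 2 samples per class for LOOCV")
    scores = np.empty(n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        scaler, clf = _fit_svm(X[mask], y[mask], spec)
        xs = scaler.transform(X[i : i + 1])
        scores[i] = float(clf.decision_function(xs)[0])
        preds[i] = int(clf.predict(xs)[0])
    counts = ConfusionCounts(
        TP=int(np.sum((preds == 1) & (y == 1))),
        FP=int(np.sum((preds == 1) & (y == 0))),
        TN=int(np.sum((preds == 0) & (y == 0))),
        FN=int(np.sum((preds == 0) & (y == 1))),
    )
    ms = confusion_metrics(counts)
    ms.auc = roc_and_auc(scores, y)[2]
    return ms, scores, counts


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, n_splits: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold accuracy used as the inner tuning/selection score."""
    n_splits = min(n_splits, int(np.min(np.bincount(y))))
    if n_splits < 2:
        raise InputError("too few samples per class for inner CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        scaler, clf = _fit_svm(X[tr], y[tr], spec)
        correct += int(np.sum(clf.predict(scaler.transform(X[te])) == y[te]))
    return correct / len(y)


def tune_hyperparameters(
    table: FeatureTable,
    kernel: str,
    features: list[str] | None = None,
    c_grid: tuple = DEFAULT_C_GRID,
    gamma_grid: tuple = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> ModelSpec:
    """Grid-search (C, gamma) by inner 5-fold CV accuracy.

    Ties resolve to the smallest C, then the smallest gamma ('scale' sorts
    first as the default rule).  Linear kernels ignore gamma.
    """
    if not c_grid:
        raise InputError("empty C grid")
    feats = features or table.feature_names
    X = table.data[feats].to_numpy(float)
    y = _encode(table.labels)
    gammas = gamma_grid if kernel == "rbf" else ("scale",)
    # iterate smallest-first so ties keep the smallest C then smallest gamma
    # ('scale', the default rule, sorts before the numeric gammas)
    gammas = sorted(gammas, key=lambda g: (-1.0 if g == "scale" else float(g)))
    best: tuple[float, ModelSpec] | None = None
    for C in sorted(c_grid):
        for g in gammas:
            spec = ModelSpec(kernel=kernel, C=C, gamma=g, features=list(feats))
            score = _cv_accuracy(X, y, spec, seed=seed)
            if best is None or score > best[0] + 1e-12:
                best = (score, spec)
    return best[1]


def forward_select(
    table: FeatureTable,
    candidates: list[str],
    spec: ModelSpec,
    scorer=None,
    epsilon: float = 1e-3,
    patience: int = 3,
    max_features: int | None = None,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Wrapper-based greedy forward feature selection.

    At each step the candidate whose addition maximizes the cross-validated
    score joins the subset; selection stops once the best improvement stays
    below ``epsilon`` for ``patience`` consecutive steps (the plateau) or
    candidates run out.  Returns the subset at the plateau point and the
    full score trajectory.
    """
    if not candidates:
        raise InputError("no candidate features")
    y = _encode(table.labels)

    def default_scorer(feats: list[str]) -> float:
        X = table.data[feats].to_numpy(float)
        return _cv_accuracy(X, y, replace(spec, features=list(feats)), seed=seed)

    score_fn = scorer or default_scorer
    remaining = list(candidates)
    selected: list[str] = []
    trajectory: list[float] = []
    best_so_far = -np.inf
    best_len = 0
    stall = 0
    while remaining:
        if max_features is not None and len(selected) >= max_features:
            break
        step = [(score_fn(selected + [f]), f) for f in remaining]
        step_best, f_best = max(step, key=lambda t: (t[0], -remaining.index(t[1])))
        selected.append(f_best)
        remaining.remove(f_best)
        trajectory.append(step_best)
        if step_best > best_so_far + epsilon:
            best_so_far = step_best
            best_len = len(selected)
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    return selected[:best_len] if best_len else selected[:1], trajectory


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------


def roc_and_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points by score thresholding and trapezoidal AUC.

    ``labels`` may be 0/1 ints or 'autism'/'control' strings.
    Returns (fpr, tpr, auc).
    """
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        y = (y == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise InputError("ROC requires both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(y, np.asarray(scores, float))
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))


def mean_roc(
    curves: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 101
) -> tuple[np.ndarray, np.ndarray, float]:
    """Vertically average ROC curves on a fixed FPR grid.

    Returns (fpr_grid, mean_tpr, auc_of_mean_curve).
    """
    if not curves:
        raise InputError("no ROC curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return grid, mean_tpr, float(np.trapezoid(mean_tpr, grid))


# --------------------------------------------------------------------------
# Summed ranking
# --------------------------------------------------------------------------

RANK_METRICS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "mcc")


def summed_rank(
    models: dict[str, MetricSet], metrics: tuple[str, ...] = RANK_METRICS
) -> pd.DataFrame:
    """Summed-rank comparison table.

    Each metric is midranked across models (rank 1 = best value); SR is the
    row sum and the final rank orders ascending SR, ties broken by higher
    accuracy then by name.  Raises if any model is missing a metric.
    """
    if len(models) < 2:
        raise InputError("summed ranking needs at least 2 models")
    rows = {}
    for name, ms in models.items():
        d = ms.as_dict()
        missing = [m for m in metrics if m not in d or d[m] is None]
        if missing:
            raise InputError(f"model {name!r} missing metrics: {missing}")
        rows[name] = {m: d[m] for m in metrics}
    df = pd.DataFrame(rows).T
    ranks = df.apply(lambda col: stats.rankdata(-col.to_numpy(), method="average"))
    df_out = df.copy()
    df_out["SR"] = ranks.sum(axis=1)
    order = df_out.sort_values(
        by=["SR", "accuracy"], ascending=[True, False], kind="mergesort"
    )
    order = order.loc[
        sorted(order.index, key=lambda n: (order.at[n, "SR"], -order.at[n, "accuracy"], n))
    ]
    order["final_rank"] = np.arange(1, len(order) + 1)
    return order
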