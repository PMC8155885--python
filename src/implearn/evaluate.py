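"""Classifier configurations, cross-validation, metrics and statistics.

The classifier battery mirrors a standard shallow-learning survey:
decision trees at three granularities (maximum of 100 / 20 / 3 leaf
nodes for fine / medium / coarse), a random forest, k-nearest-neighbors
with Minkowski distance at k = 1 / 3 / 20 plus a cosine-distance
variant, and SVMs with linear, quadratic, cubic and Gaussian-RBF
kernels.  Training is delegated to scikit-learn; this module owns the
configurations, stratified k-fold evaluation, confusion-matrix metrics
(fast = positive class), ROC curves, and the with/without-selection
t-test.  Distance- and margin-based learners (kNN, SVM) are z-scored
with statistics fit on the training folds only; trees are not scaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ParameterError, StratificationError
from .features import FeatureTable

__all__ = ["ClassifierSpec", "CLASSIFIER_SPECS", "get_spec", "EvalResult",
           "confusion_metrics", "cv_accuracy", "make_cv_fitness",
           "evaluate_full", "roc_points", "median_roc", "compare_abc",
           "TTestResult"]

POSITIVE = "fast"  # sensitivity = correctly classified fast events


@dataclass(frozen=True)
class ClassifierSpec:
    """A named, complete classifier configuration."""

    family: str
    variant: str
    params: dict = field(default_factory=dict, hash=False)

    @property
    def name(self) -> str:
        return f"{self.family}-{self.variant}" if self.variant else self.family

    def build(self, seed: int | None = None):
        """Instantiate the scikit-learn estimator for this spec."""
        if self.family == "decision_tree":
            est = DecisionTreeClassifier(
                max_leaf_nodes=self.params["max_nodes"], random_state=seed)
            return est
        if self.family == "random_forest":
            return RandomForestClassifier(n_estimators=100, random_state=seed)
        if self.family == "knn":
            est = KNeighborsClassifier(
                n_neighbors=self.params["n_neighbors"],
                metric=self.params.get("metric", "minkowski"))
            return Pipeline([("scale", StandardScaler()), ("clf", est)])
        if self.family == "svm":
            est = SVC(kernel=self.params["kernel"],
                      degree=self.params.get("degree", 3),
                      random_state=seed)
            return Pipeline([("scale", StandardScaler()), ("clf", est)])
        raise ParameterError(f"unknown classifier family {self.family!r}")


CLASSIFIER_SPECS: dict[str, ClassifierSpec] = {
    "random-forest": ClassifierSpec("random_forest", ""),
    "tree-fine": ClassifierSpec("decision_tree", "fine", {"max_nodes": 100}),
    "tree-medium": ClassifierSpec("decision_tree", "medium", {"max_nodes": 20}),
    "tree-coarse": ClassifierSpec("decision_tree", "coarse", {"max_nodes": 3}),
    "knn-fine": ClassifierSpec("knn", "fine", {"n_neighbors": 1}),
    "knn-medium": ClassifierSpec("knn", "medium", {"n_neighbors": 3}),
    "knn-coarse": ClassifierSpec("knn", "coarse", {"n_neighbors": 20}),
    # neighbor count for the cosine variant follows the common toolbox
    # preset of 10 (not stated alongside the 1/3/20 Minkowski variants)
    "knn-cosine": ClassifierSpec("knn", "cosine",
                                 {"n_neighbors": 10, "metric": "cosine"}),
    "svm-linear": ClassifierSpec("svm", "linear", {"kernel": "linear"}),
    "svm-poly": ClassifierSpec("svm", "poly", {"kernel": "poly", "degree": 2}),
    "svm-cubic": ClassifierSpec("svm", "cubic", {"kernel": "poly", "degree": 3}),
    "svm-rbf": ClassifierSpec("svm", "rbf", {"kernel": "rbf"}),
}


def get_spec(name: "str | ClassifierSpec") -> ClassifierSpec:
    if isinstance(name, ClassifierSpec):
        return name
    try:
        return CLASSIFIER_SPECS[name]
    except KeyError:
        raise ParameterError(
            f"unknown classifier {name!r}; choose from {sorted(CLASSIFIER_SPECS)}"
        ) from None


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN) (fast recalled),
    specificity = TN/(TN+FP).
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ParameterError("empty confusion matrix")
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def _xy(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    if table.X.shape[1] == 0:
        raise ParameterError("feature table has no columns (empty selection)")
    y = (table.y == POSITIVE).to_numpy(dtype=int)
    return table.X.to_numpy(dtype=float), y


def _folds(y: np.ndarray, k: int, seed: int):
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise StratificationError(
            f"minority class has {counts.min()} rows, cannot stratify {k} folds"
        )
    return StratifiedKFold(n_splits=k, shuffle=True,
                           random_state=int(seed) % (2**32 - 1))


def cv_accuracy(table: FeatureTable, spec: "str | ClassifierSpec",
                k: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy over k stratified folds (deterministic).

    This is the selection fitness: the colony scores every candidate
    bit vector with this quantity on the masked table.
    """
    spec = get_spec(spec)
    X, y = _xy(table)
    skf = _folds(y, k, seed)
    accs = []
    for train, test in skf.split(X, y):
        est = spec.build(seed=int(seed) % (2**31 - 1))
        est.fit(X[train], y[train])
        accs.append(accuracy_score(y[test], est.predict(X[test])))
    return float(np.mean(accs))


def make_cv_fitness(spec: "str | ClassifierSpec" = "knn-coarse",
                    k: int = 5, seed: int = 0):
    """Bind cv_accuracy into a fitness callable for the optimizer."""
    spec = get_spec(spec)
    return lambda table: cv_accuracy(table, spec, k=k, seed=seed)


@dataclass
class EvalResult:
    """Repeated-CV evaluation: per-repeat metrics and their summary.

    ``per_repeat`` has one row per repetition with pooled confusion
    counts and the three metrics; ``summary`` maps each metric to best /
    upper quartile / median / lower quartile / worst / mean / sd;
    ``median_confusion`` is the element-wise median of the per-repeat
    pooled confusion matrices.
    """

    spec: ClassifierSpec
    per_repeat: pd.DataFrame = field(repr=False)
    summary: dict[str, dict[str, float]]
    median_confusion: dict[str, float]

    @property
    def accuracies(self) -> np.ndarray:
        return self.per_repeat["accuracy"].to_numpy()


def _summary(values: np.ndarray) -> dict[str, float]:
    q = np.percentile(values, [100, 75, 50, 25, 0])
    return {"best": float(q[0]), "q3": float(q[1]), "median": float(q[2]),
            "q1": float(q[3]), "worst": float(q[4]),
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0}


def evaluate_full(table: FeatureTable, spec: "str | ClassifierSpec",
                  k: int = 5, repeats: int = 5, seed: int = 0,
                  pooled: bool = True) -> EvalResult:
    """``repeats`` independent stratified-CV runs with derived seeds.

    Each repeat pools held-out predictions across its k folds into one
    confusion matrix (``pooled=False`` averages per-fold metrics
    instead).  The summary layout reports best, quartiles, median, mean
    and SD of each metric over repeats.
    """
    if repeats < 1:
        raise ParameterError(f"repeats must be >= 1, got {repeats}")
    spec = get_spec(spec)
    X, y = _xy(table)
    rows = []
    for rep in range(repeats):
        rep_seed = (int(seed) + 7919 * rep) % (2**31 - 1)
        skf = _folds(y, k, rep_seed)
        tp = fp = tn = fn = 0
        fold_metrics = []
        for train, test in skf.split(X, y):
            est = spec.build(seed=rep_seed)
            est.fit(X[train], y[train])
            pred = est.predict(X[test])
            f_tp = int(((pred == 1) & (y[test] == 1)).sum())
            f_fp = int(((pred == 1) & (y[test] == 0)).sum())
            f_tn = int(((pred == 0) & (y[test] == 0)).sum())
            f_fn = int(((pred == 0) & (y[test] == 1)).sum())
            tp, fp, tn, fn = tp + f_tp, fp + f_fp, tn + f_tn, fn + f_fn
            fold_metrics.append(confusion_metrics(f_tp, f_fp, f_tn, f_fn))
        if pooled:
            metrics = confusion_metrics(tp, fp, tn, fn)
        else:
            metrics = {m: float(np.mean([fm[m] for fm in fold_metrics]))
                       for m in ("accuracy", "sensitivity", "specificity")}
        rows.append({"repeat": rep, "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                     **metrics})
    per_repeat = pd.DataFrame(rows)
    summary = {m: _summary(per_repeat[m].to_numpy())
               for m in ("accuracy", "sensitivity", "specificity")}
    median_confusion = {c: float(per_repeat[c].median())
                        for c in ("tp", "fp", "tn", "fn")}
    return EvalResult(spec=spec, per_repeat=per_repeat, summary=summary,
                      median_confusion=median_confusion)


def _scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    if hasattr(est, "decision_function"):
        return est.decision_function(X)
    raise ParameterError(f"classifier {est!r} exposes no continuous score")


def roc_points(table: FeatureTable, spec: "str | ClassifierSpec",
               k: int = 5, seed: int = 0) -> pd.DataFrame:
    """Pooled-fold ROC curve: (fpr, tpr) points swept over scores.

    Held-out scores from all k folds are pooled and thresholded at every
    unique score; the curve starts at (0, 0) and ends at (1, 1).
    """
    spec = get_spec(spec)
    X, y = _xy(table)
    skf = _folds(y, k, seed)
    scores = np.empty_like(y, dtype=float)
    for train, test in skf.split(X, y):
        est = spec.build(seed=int(seed) % (2**31 - 1))
        est.fit(X[train], y[train])
        scores[test] = _scores(est, X[test])
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def median_roc(table: FeatureTable, spec: "str | ClassifierSpec",
               k: int = 5, repeats: int = 5, seed: int = 0,
               grid: int = 101) -> pd.DataFrame:
    """Pointwise median of ``repeats`` ROC curves on a common FPR grid."""
    fgrid = np.linspace(0, 1, grid)
    curves = []
    for rep in range(repeats):
        pts = roc_points(table, spec, k=k, seed=(int(seed) + 7919 * rep))
        curves.append(np.interp(fgrid, pts["fpr"], pts["tpr"]))
    return pd.DataFrame({"fpr": fgrid, "tpr": np.median(curves, axis=0)})


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def compare_abc(with_abc, without_abc, mode: str = "paired") -> TTestResult:
    """Two-sided t-test between with- and without-selection accuracies.

    ``paired`` (default) treats repeats as matched, df = n - 1;
    ``independent`` uses the pooled-variance two-sample test,
    df = 2n - 2.  Identical samples return t = 0, p = 1.
    """
    a = np.asarray(with_abc, dtype=float)
    b = np.asarray(without_abc, dtype=float)
    if a.size != b.size:
        raise ParameterError(f"unequal repeat counts: {a.size} vs {b.size}")
    if a.size < 2:
        raise ParameterError("need at least 2 repeats per group")
    n = a.size
    if mode == "paired":
        diff = a - b
        sd = diff.std(ddof=1)
        df = n - 1
        if sd == 0:
            if diff.mean() == 0:
                return TTestResult(0.0, df, 1.0)
            return TTestResult(float(np.sign(diff.mean()) * np.inf), df, 0.0)
        t = diff.mean() / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), df)
        return TTestResult(float(t), df, float(p))
    if mode == "independent":
        df = 2 * n - 2
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        if sp2 == 0:
            if a.mean() == b.mean():
                return TTestResult(0.0, df, 1.0)
            return TTestResult(float(np.sign(a.mean() - b.mean()) * np.inf),
                               df, 0.0)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * 2 / n)
        p = 2 * stats.t.sf(abs(t), df)
        return TTestResult(float(t), df, float(p))
    raise ParameterError(f"unknown mode {mode!r}")
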