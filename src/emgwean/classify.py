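"""Weaning-outcome classification: NB / KNN / SVM with backward elimination.

Three classical classifiers are evaluated with repeated stratified random
70/30 splits: a per-class Gaussian Naive Bayes (independent features), a
k-nearest-neighbour voter over a configurable distance metric (including a
Spearman distance implemented as correlation distance on rank-transformed
features), and a maximum-margin SVM with a polynomial kernel (degree 5 by
default).  Weaning *success* is the positive class throughout, which pins
the sensitivity/specificity semantics.

Sequential backward elimination removes, at each step, the feature whose
removal maximises mean accuracy (the feature with the least impact), and
returns the subset with the global best mean accuracy over the trace.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import feature_columns

logger = logging.getLogger("emgwean")

POSITIVE = "success"
NEGATIVE = "failure"

KNN_METRICS = ("cityblock", "chebyshev", "correlation", "cosine",
               "euclidean", "hamming", "jaccard", "mahalanobis",
               "minkowski", "spearman")


@dataclasses.dataclass
class ClassifierSpec:
    kind: str = "naive_bayes"           # naive_bayes | knn | svm
    knn_k: int = 5
    knn_metric: str = "spearman"
    svm_degree: int = 5
    svm_c: float = 1.0

    def __post_init__(self):
        if self.kind not in ("naive_bayes", "knn", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn k must be odd and >= 1")
        if self.knn_metric not in KNN_METRICS:
            raise ValueError(f"unknown KNN metric {self.knn_metric!r}")
        if self.svm_degree < 1:
            raise ValueError("svm degree must be >= 1")


@dataclasses.dataclass
class EvalReport:
    classifier: str
    features: list
    n_runs: int
    seed: int
    accuracy: tuple          # (mean, sd)
    specificity: tuple
    sensitivity: tuple
    f_score: tuple
    confusion: np.ndarray    # [[TP, FN], [FP, TN]] summed over runs
    n_redraws: int = 0
    per_run: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "features": list(self.features),
            "n_runs": self.n_runs,
            "seed": self.seed,
            "accuracy_mean": self.accuracy[0], "accuracy_sd": self.accuracy[1],
            "specificity_mean": self.specificity[0],
            "specificity_sd": self.specificity[1],
            "sensitivity_mean": self.sensitivity[0],
            "sensitivity_sd": self.sensitivity[1],
            "f_score_mean": self.f_score[0], "f_score_sd": self.f_score[1],
            "confusion": self.confusion.tolist(),
            "n_redraws": self.n_redraws,
        }


def _zscore_train_test(xtr, xte):
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (xtr - mu) / sd, (xte - mu) / sd


def train_predict(spec: ClassifierSpec, x_train: np.ndarray, y_train,
                  x_test: np.ndarray) -> np.ndarray:
    """Fit the configured classifier and predict labels for ``x_test``.

    Features are z-scored with training-fold statistics for KNN and SVM;
    Naive Bayes consumes raw features (its per-class Gaussians absorb
    scale).
    """
    y_train = np.asarray(y_train)
    if len(set(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.atleast_2d(np.asarray(x_test, dtype=float))

    if spec.kind == "naive_bayes":
        model = GaussianNB()
        model.fit(x_train, y_train)
        return model.predict(x_test)

    xtr, xte = _zscore_train_test(x_train, x_test)
    if spec.kind == "knn":
        k = min(spec.knn_k, len(y_train))
        if spec.knn_metric == "spearman":
            # Spearman distance: correlation distance on per-sample ranks
            xtr = stats.rankdata(xtr, axis=1)
            xte = stats.rankdata(xte, axis=1)
            metric = "correlation"
        elif spec.knn_metric == "mahalanobis":
            cov = np.cov(xtr, rowvar=False)
            cov += 1e-6 * np.eye(cov.shape[0])
            model = KNeighborsClassifier(
                n_neighbors=k, metric="mahalanobis", metric_params={"VI": np.linalg.inv(cov)}
            )
            model.fit(xtr, y_train)
            return model.predict(xte)
        else:
            metric = spec.knn_metric
        model = KNeighborsClassifier(n_neighbors=k, metric=metric)
        model.fit(xtr, y_train)
        return model.predict(xte)

    model = SVC(kernel="poly", degree=spec.svm_degree, C=spec.svm_c,
                gamma="scale", coef0=1.0)
    model.fit(xtr, y_train)
    return model.predict(xte)


def confusion(y_true, y_pred) -> np.ndarray:
    """2x2 confusion counts [[TP, FN], [FP, TN]], success = positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE)))
    fn = int(np.sum((y_true == POSITIVE) & (y_pred != POSITIVE)))
    fp = int(np.sum((y_true != POSITIVE) & (y_pred == POSITIVE)))
    tn = int(np.sum((y_true != POSITIVE) & (y_pred != POSITIVE)))
    return np.array([[tp, fn], [fp, tn]])


def metrics(conf: np.ndarray) -> dict:
    """Accuracy / specificity / sensitivity / F-score from a 2x2 matrix.

    Undefined ratios (zero denominators) are NaN and excluded from
    run-averaging upstream.
    """
    (tp, fn), (fp, tn) = np.asarray(conf)
    total = tp + fn + fp + tn
    if total <= 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f = (2 * prec * sens / (prec + sens)
         if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
         else float("nan"))
    return {"accuracy": (tp + tn) / total, "specificity": spec,
            "sensitivity": sens, "f_score": f}


def _stratified_split(y, train_frac, rng):
    y = np.asarray(y)
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_tr = int(round(train_frac * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)
        train_idx.extend(idx[:n_tr])
        test_idx.extend(idx[n_tr:])
    return np.asarray(train_idx), np.asarray(test_idx)


def evaluate(matrix: pd.DataFrame, spec: ClassifierSpec, features=None,
             n_runs: int = 1000, train_frac: float = 0.7, seed: int = 0,
             keep_per_run: bool = False) -> EvalReport:
    """Repeated stratified random-split evaluation.

    Per run: stratified ``train_frac`` split, train, predict, score.  The
    report carries mean +- SD of the four metrics over runs (NaN metrics
    excluded per-metric) and the run-summed confusion matrix.
    """
    feats = list(features) if features is not None else feature_columns(matrix)
    x = matrix[feats].to_numpy(dtype=float)
    y = matrix["group"].to_numpy()
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValueError("both classes need at least 2 members")
    x = np.nan_to_num(x, nan=0.0)

    rng = np.random.default_rng(seed)
    per_run = []
    conf_total = np.zeros((2, 2), dtype=int)
    redraws = 0
    for _ in range(n_runs):
        for _attempt in range(100):
            tr, te = _stratified_split(y, train_frac, rng)
            if len(set(y[te])) == 2:
                break
            redraws += 1
        y_pred = train_predict(spec, x[tr], y[tr], x[te])
        conf = confusion(y[te], y_pred)
        conf_total += conf
        per_run.append(metrics(conf))
    df = pd.DataFrame(per_run)

    def agg(col):
        v = df[col].dropna()
        if v.empty:
            return (float("nan"), float("nan"))
        return (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)

    if redraws:
        logger.info("evaluate: %d split redraws (test fold lacked a class)",
                    redraws)
    return EvalReport(
        classifier=spec.kind, features=feats, n_runs=n_runs, seed=seed,
        accuracy=agg("accuracy"), specificity=agg("specificity"),
        sensitivity=agg("sensitivity"), f_score=agg("f_score"),
        confusion=conf_total, n_redraws=redraws,
        per_run=df if keep_per_run else None,
    )


def sequential_backward_elimination(matrix: pd.DataFrame,
                                    spec: ClassifierSpec, features=None,
                                    n_runs: int = 100,
                                    train_frac: float = 0.7,
                                    seed: int = 0) -> dict:
    """Backward elimination by least impact on mean accuracy.

    At each step every remaining feature's removal is scored with
    :func:`evaluate` (at the reduced ``n_runs``); the removal with the
    highest resulting accuracy is applied (ties toward the lowest catalog
    index).  Returns the elimination trace and the attribute set with the
    global best accuracy, which by construction never scores below the full
    set.
    """
    feats = list(features) if features is not None else feature_columns(matrix)
    if len(feats) < 2:
        raise ValueError("need at least 2 features to eliminate")
    current = list(feats)
    full = evaluate(matrix, spec, current, n_runs, train_frac, seed)
    trace = [{"removed": None, "features": list(current),
              "accuracy": full.accuracy[0]}]
    best_set, best_acc = list(current), full.accuracy[0]
    step_seed = seed
    while len(current) > 1:
        step_seed += 1
        scores = []
        for f in current:
            cand = [c for c in current if c != f]
            rep = evaluate(matrix, spec, cand, n_runs, train_frac, step_seed)
            scores.append(rep.accuracy[0])
        i = int(np.argmax(scores))      # first max = lowest catalog index
        removed = current.pop(i)
        trace.append({"removed": removed, "features": list(current),
                      "accuracy": scores[i]})
        if scores[i] > best_acc:
            best_acc = scores[i]
            best_set = list(current)
        logger.info("elimination: removed %s (acc %.3f, %d left)",
                    removed, scores[i], len(current))
    return {"trace": trace, "best_features": best_set,
            "best_accuracy": best_acc}
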