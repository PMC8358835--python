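"""Classification and evaluation harness.

Backends: an L2-regularized logistic regression (negative log-likelihood of
the sigmoid model plus a squared-weight penalty, bias unpenalized), a ridge
classifier on one-hot indicators, and a linear-kernel SVM delegated to
scikit-learn.  Evaluation is stratified k-fold cross-validation (repeated),
or an 80/20 stratified holdout.  Features are z-scored with training-fold
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .connectivity import FeatureSet

__all__ = [
    "ClassifierModel",
    "EvalReport",
    "fit_logistic_l2",
    "fit_ridge",
    "fit_svm",
    "predict",
    "cross_validate",
    "holdout_evaluate",
    "confusion_and_metrics",
    "BACKENDS",
]


@dataclass
class ClassifierModel:
    """Linear classifier: per-class weight rows, bias, and backend tag.

    Multi-class prediction is argmax of the per-class linear scores; ties
    break toward the lowest class index.
    """

    weights: np.ndarray  # (c, d) — one row per class (binary: 2 rows)
    bias: np.ndarray  # (c,)
    reg_strength: float
    backend: str
    classes: np.ndarray
    _sk_model: Any = None

    def __post_init__(self) -> None:
        if self.backend != "svm" and self.reg_strength < 0:
            raise ValueError("reg_strength must be >= 0")


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, columns = predicted) with derived metrics."""

    confusion: np.ndarray
    classes: list
    precision: dict
    recall: dict
    accuracy: float
    repeats: list[float] = field(default_factory=list)
    mean_sd: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "accuracy": self.accuracy,
            "repeats": list(self.repeats),
            "mean_sd": list(self.mean_sd) if self.mean_sd is not None else None,
        }

    def to_text(self) -> str:
        lines = ["confusion (rows=true, cols=predicted):"]
        header = "\t".join([""] + [str(c) for c in self.classes])
        lines.append(header)
        for c, row in zip(self.classes, self.confusion):
            lines.append("\t".join([str(c)] + [str(int(v)) for v in row]))
        for c in self.classes:
            p = self.precision.get(c)
            r = self.recall.get(c)
            lines.append(
                f"class {c}: precision="
                f"{'n/a' if p is None else f'{p:.4f}'} "
                f"recall={'n/a' if r is None else f'{r:.4f}'}"
            )
        lines.append(f"accuracy: {self.accuracy:.4f}")
        if self.mean_sd is not None:
            lines.append(f"repeats: {self.mean_sd[0]:.4f} +/- {self.mean_sd[1]:.4f}")
        return "\n".join(lines)


def _check_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    return classes


def _nll_grad(params, X, t, reg):
    """Penalized negative log-likelihood of the sigmoid model and its gradient."""
    w, b = params[:-1], params[-1]
    z = X @ w + b
    # log(1 + exp(-t*z)) computed stably
    m = np.maximum(0.0, -t * z)
    nll = float(np.sum(m + np.log(np.exp(-m) + np.exp(-t * z - m))))
    nll += reg * float(w @ w)
    p = 1.0 / (1.0 + np.exp(-(t * z)))
    coef = -t * (1.0 - p)
    grad_w = X.T @ coef + 2.0 * reg * w
    grad_b = float(coef.sum())
    return nll, np.concatenate([grad_w, [grad_b]])


def fit_logistic_l2(features: FeatureSet, reg_strength: float = 1.0) -> ClassifierModel:
    """One-vs-rest L2-penalized logistic regression (bias unpenalized)."""
    X, y = features.X, features.labels
    classes = _check_classes(y)
    d = X.shape[1]
    W = np.zeros((classes.size, d))
    b = np.zeros(classes.size)
    for ci, c in enumerate(classes):
        t = np.where(y == c, 1.0, -1.0)
        res = optimize.minimize(
            _nll_grad,
            np.zeros(d + 1),
            args=(X, t, reg_strength),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
        )
        W[ci] = res.x[:-1]
        b[ci] = res.x[-1]
    return ClassifierModel(
        weights=W, bias=b, reg_strength=reg_strength, backend="logistic_l2",
        classes=classes,
    )


def fit_ridge(features: FeatureSet, reg_strength: float = 1.0) -> ClassifierModel:
    """Ridge classifier: penalized least squares on one-hot indicators.

    The bias is left unpenalized by augmenting the design with a constant
    column excluded from the penalty.
    """
    X, y = features.X, features.labels
    classes = _check_classes(y)
    n, d = X.shape
    Y = np.zeros((n, classes.size))
    for ci, c in enumerate(classes):
        Y[y == c, ci] = 1.0
    Xa = np.hstack([X, np.ones((n, 1))])
    P = np.eye(d + 1) * reg_strength
    P[-1, -1] = 0.0
    coef = np.linalg.lstsq(Xa.T @ Xa + P, Xa.T @ Y, rcond=None)[0]
    return ClassifierModel(
        weights=coef[:-1].T, bias=coef[-1].copy(), reg_strength=reg_strength,
        backend="ridge", classes=classes,
    )


def fit_svm(features: FeatureSet, C: float = 1.0) -> ClassifierModel:
    """Linear-kernel SVM baseline delegated to scikit-learn."""
    from sklearn.svm import SVC

    X, y = features.X, features.labels
    classes = _check_classes(y)
    model = SVC(kernel="linear", C=C, decision_function_shape="ovr")
    model.fit(X, y)
    return ClassifierModel(
        weights=np.zeros((classes.size, X.shape[1])), bias=np.zeros(classes.size),
        reg_strength=C, backend="svm", classes=classes, _sk_model=model,
    )


def predict(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Predict labels; argmax over class scores, ties to the lowest class index."""
    X = np.asarray(X, dtype=float)
    if model.backend == "svm":
        return model._sk_model.predict(X)
    scores = X @ model.weights.T + model.bias
    return model.classes[np.argmax(scores, axis=1)]


BACKENDS = {
    "logistic_l2": fit_logistic_l2,
    "ridge": fit_ridge,
    "svm": fit_svm,
}


def confusion_and_metrics(
    true_labels, predicted_labels, classes=None
) -> EvalReport:
    """Confusion counts with per-class precision/recall and accuracy.

    Precision for a class nobody was assigned to (empty column) is
    reported as ``None`` (absent), not 0.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if classes is None:
        classes = np.unique(np.concatenate([t, p]))
    classes = np.asarray(classes)
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((classes.size, classes.size), dtype=int)
    for ti, pi in zip(t, p):
        conf[idx[ti], idx[pi]] += 1
    precision, recall = {}, {}
    for ci, c in enumerate(classes):
        col = conf[:, ci].sum()
        row = conf[ci, :].sum()
        precision[c] = float(conf[ci, ci] / col) if col > 0 else None
        recall[c] = float(conf[ci, ci] / row) if row > 0 else None
    accuracy = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    return EvalReport(
        confusion=conf, classes=list(classes), precision=precision,
        recall=recall, accuracy=accuracy,
    )


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Yield (train_idx, test_idx) with per-class round-robin assignment."""
    assignments = np.empty(y.shape[0], dtype=int)
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        if members.size < folds:
            raise ValueError(
                f"class {c!r} has {members.size} samples, fewer than {folds} folds"
            )
        members = rng.permutation(members)
        assignments[members] = np.arange(members.size) % folds
    for f in range(folds):
        yield np.flatnonzero(assignments != f), np.flatnonzero(assignments == f)


def _zscore_train_test(Xtr, Xte):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def cross_validate(
    features: FeatureSet,
    backend: str = "logistic_l2",
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    reg_strength: float = 1.0,
) -> EvalReport:
    """Repeated stratified k-fold CV; fully reproducible from ``seed``.

    Each sample is predicted exactly once per repeat.  The confusion
    matrix aggregates every held-out prediction across repeats; the
    accuracy distribution over repeats gives ``mean_sd``.
    """
    if backend not in BACKENDS:
        raise ValueError(f"unknown backend {backend!r}")
    X, y = features.X, features.labels
    _check_classes(y)
    rng = np.random.default_rng(seed)
    all_true, all_pred = [], []
    repeat_acc = []
    for _ in range(repeats):
        rep_true, rep_pred = [], []
        for train, test in _stratified_folds(y, folds, rng):
            Xtr, Xte = _zscore_train_test(X[train], X[test])
            sub = FeatureSet(
                X=Xtr, labels=y[train],
                feature_names=features.feature_names,
            )
            model = BACKENDS[backend](sub, reg_strength)
            pred = predict(model, Xte)
            rep_true.append(y[test])
            rep_pred.append(pred)
        rep_true = np.concatenate(rep_true)
        rep_pred = np.concatenate(rep_pred)
        repeat_acc.append(float(np.mean(rep_true == rep_pred)))
        all_true.append(rep_true)
        all_pred.append(rep_pred)
    report = confusion_and_metrics(
        np.concatenate(all_true), np.concatenate(all_pred), classes=np.unique(y)
    )
    report.repeats = repeat_acc
    report.mean_sd = (float(np.mean(repeat_acc)), float(np.std(repeat_acc)))
    return report


def holdout_evaluate(
    features: FeatureSet,
    backend: str = "logistic_l2",
    test_frac: float = 0.2,
    seed: int = 0,
    reg_strength: float = 1.0,
) -> EvalReport:
    """Single stratified holdout split (default 80/20 train/test)."""
    X, y = features.X, features.labels
    _check_classes(y)
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(y.shape[0], dtype=bool)
    for c in np.unique(y):
        members = rng.permutation(np.flatnonzero(y == c))
        n_test = max(1, int(round(test_frac * members.size)))
        test_mask[members[:n_test]] = True
    train = np.flatnonzero(~test_mask)
    test = np.flatnonzero(test_mask)
    Xtr, Xte = _zscore_train_test(X[train], X[test])
    sub = FeatureSet(X=Xtr, labels=y[train], feature_names=features.feature_names)
    model = BACKENDS[backend](sub, reg_strength)
    pred = predict(model, Xte)
    report = confusion_and_metrics(y[test], pred, classes=np.unique(y))
    report.repeats = [report.accuracy]
    report.mean_sd = (report.accuracy, 0.0)
    return report
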