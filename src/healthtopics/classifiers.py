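"""The three classification techniques behind one train/predict contract.

* ``naive_bayes`` -- Bernoulli naive Bayes, authored here: class priors are
  count ratios; per-class feature presence probabilities use add-alpha
  smoothing, (n_present + alpha) / (n_class + 2 alpha).
* ``decision_tree`` -- a C4.5-style tree, authored here: binary splits on
  feature presence chosen by gain ratio (information gain / split
  information); pre-pruning via ``min_leaf``; leaves predict the majority
  class.
* ``svm`` -- maximum-margin classifier with polynomial kernel
  (x.y + 1)^degree, one-vs-rest for multiclass, delegated to scikit-learn's
  SVC behind this contract.

Ties everywhere break to the first class in class order (the corpus's
first-appearance label order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix
from .selection import information_gain_matrix, _xlogx

__all__ = [
    "ClassifierModel",
    "train_naive_bayes",
    "train_decision_tree",
    "train_svm",
    "predict",
    "predict_scores",
    "save_model",
    "load_model",
]

MatrixLike = Union[FeatureMatrix, np.ndarray, sp.spmatrix]


@dataclass
class ClassifierModel:
    """A fitted classifier: kind, class order, and kind-specific payload."""

    kind: str
    classes: list
    n_features: int
    payload: object
    provenance: dict = field(default_factory=dict)


def _as_array(matrix: MatrixLike) -> sp.csr_matrix:
    if isinstance(matrix, FeatureMatrix):
        return matrix.matrix
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.atleast_2d(np.asarray(matrix)))


def _encode_labels(labels: Sequence, class_order: Optional[Sequence]) -> tuple[list, np.ndarray]:
    labels = list(labels)
    if any(lab is None for lab in labels):
        raise ValueError("all training rows must be labeled")
    if class_order is None:
        class_order = []
        for lab in labels:
            if lab not in class_order:
                class_order.append(lab)
    class_order = list(class_order)
    index = {lab: i for i, lab in enumerate(class_order)}
    try:
        y = np.asarray([index[lab] for lab in labels])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in class order") from exc
    return class_order, y


# ---------------------------------------------------------------------------
# Bernoulli naive Bayes
# ---------------------------------------------------------------------------


def train_naive_bayes(
    matrix: MatrixLike,
    labels: Sequence,
    alpha: float = 1.0,
    class_order: Optional[Sequence] = None,
) -> ClassifierModel:
    """Fit a Bernoulli naive Bayes model on binary presence features."""
    X = _as_array(matrix)
    classes, y = _encode_labels(labels, class_order)
    n, F = X.shape
    if n == 0:
        raise ValueError("cannot train on an empty corpus")
    if len(y) != n:
        raise ValueError("labels length must equal number of rows")
    m = len(classes)
    Xb = X.astype(bool).astype(np.float64)
    counts = np.zeros(m)
    present = np.zeros((m, F))
    for c in range(m):
        rows = y == c
        counts[c] = rows.sum()
        if counts[c] == 0:
            raise ValueError(f"class {classes[c]!r} has no training documents")
        present[c] = np.asarray(Xb[rows].sum(axis=0)).ravel()
    theta = (present + alpha) / (counts[:, None] + 2.0 * alpha)
    payload = {
        "log_prior": np.log(counts / n),
        "log_theta": np.log(theta),
        "log_one_minus_theta": np.log1p(-theta),
    }
    return ClassifierModel(
        kind="naive_bayes",
        classes=classes,
        n_features=F,
        payload=payload,
        provenance={"alpha": alpha},
    )


def _nb_scores(model: ClassifierModel, X: sp.csr_matrix) -> np.ndarray:
    p = model.payload
    lt, lnt = p["log_theta"], p["log_one_minus_theta"]
    Xb = X.astype(bool).astype(np.float64)
    # log P(x|c) = sum_j x_j log theta + (1-x_j) log(1-theta)
    base = lnt.sum(axis=1)  # all-absent log-likelihood per class
    return p["log_prior"] + base + np.asarray(Xb @ (lt - lnt).T)


# ---------------------------------------------------------------------------
# Gain-ratio decision tree (C4.5-style)
# ---------------------------------------------------------------------------


def _entropy(y: np.ndarray, m: int) -> float:
    if y.size == 0:
        return 0.0
    p = np.bincount(y, minlength=m) / y.size
    return float(-_xlogx(p, 2.0).sum())


def _best_split(X: np.ndarray, y: np.ndarray, m: int, min_leaf: int) -> Optional[int]:
    """Feature index with maximal gain ratio among positive-gain splits
    whose children both hold >= min_leaf documents; None if no candidate.
    Ties break to the lowest feature index."""
    n = y.size
    parent_h = _entropy(y, m)
    n_present = X.sum(axis=0)
    n_absent = n - n_present
    best_j, best_gr = None, 0.0
    gains = information_gain_matrix(X, y)
    for j in range(X.shape[1]):
        if n_present[j] < min_leaf or n_absent[j] < min_leaf:
            continue
        gain = gains[j]
        if gain <= 1e-12:
            continue
        split_p = np.array([n_present[j] / n, n_absent[j] / n])
        split_info = float(-_xlogx(split_p, 2.0).sum())
        if split_info <= 0:
            continue
        gr = gain / split_info
        if gr > best_gr + 1e-12:
            best_j, best_gr = j, gr
    return best_j


def _majority(y: np.ndarray, m: int) -> int:
    counts = np.bincount(y, minlength=m)
    return int(np.argmax(counts))  # argmax breaks ties to the lowest index


def _grow_tree(X: np.ndarray, y: np.ndarray, m: int, min_leaf: int) -> dict:
    if np.unique(y).size == 1 or y.size < 2 * min_leaf:
        return {"leaf": _majority(y, m)}
    j = _best_split(X, y, m, min_leaf)
    if j is None:
        return {"leaf": _majority(y, m)}
    present = X[:, j].astype(bool)
    return {
        "feature": int(j),
        "absent": _grow_tree(X[~present], y[~present], m, min_leaf),
        "present": _grow_tree(X[present], y[present], m, min_leaf),
    }


def train_decision_tree(
    matrix: MatrixLike,
    labels: Sequence,
    min_leaf: int = 2,
    class_order: Optional[Sequence] = None,
) -> ClassifierModel:
    """Fit a gain-ratio decision tree on binary presence features."""
    X = np.asarray(_as_array(matrix).todense()).astype(np.uint8)
    classes, y = _encode_labels(labels, class_order)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty corpus")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    tree = _grow_tree(X, y, len(classes), min_leaf)
    return ClassifierModel(
        kind="decision_tree",
        classes=classes,
        n_features=X.shape[1],
        payload=tree,
        provenance={"min_leaf": min_leaf},
    )


def _tree_predict_one(tree: dict, x: np.ndarray) -> int:
    node = tree
    while "leaf" not in node:
        node = node["present"] if x[node["feature"]] else node["absent"]
    return node["leaf"]


# ---------------------------------------------------------------------------
# Polynomial-kernel SVM (delegated solver)
# ---------------------------------------------------------------------------


def train_svm(
    matrix: MatrixLike,
    labels: Sequence,
    degree: int = 1,
    C: float = 1.0,
    class_order: Optional[Sequence] = None,
) -> ClassifierModel:
    """Fit a one-vs-rest SVM with the polynomial kernel (x.y + 1)^degree."""
    X = _as_array(matrix).astype(np.float64)
    classes, y = _encode_labels(labels, class_order)
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty corpus")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if C <= 0:
        raise ValueError("C must be > 0")
    est = OneVsRestClassifier(
        SVC(kernel="poly", degree=degree, C=C, coef0=1.0, gamma=1.0)
    )
    est.fit(X, y)
    return ClassifierModel(
        kind="svm",
        classes=classes,
        n_features=X.shape[1],
        payload=est,
        provenance={"degree": degree, "C": C},
    )


# ---------------------------------------------------------------------------
# Shared prediction contract
# ---------------------------------------------------------------------------


def predict_scores(model: ClassifierModel, matrix: MatrixLike) -> Optional[np.ndarray]:
    """Per-class scores where the kind provides them (log-posteriors for
    naive Bayes, decision values for the SVM; None for the tree)."""
    X = _check_dims(model, matrix)
    if model.kind == "naive_bayes":
        return _nb_scores(model, X)
    if model.kind == "svm":
        df = model.payload.decision_function(X.astype(np.float64))
        return df if df.ndim == 2 else np.column_stack([-df, df])
    return None


def predict(model: ClassifierModel, matrix: MatrixLike) -> list:
    """Predicted label per row; deterministic, ties to the first class."""
    X = _check_dims(model, matrix)
    if model.kind == "naive_bayes":
        idx = np.argmax(_nb_scores(model, X), axis=1)
    elif model.kind == "decision_tree":
        dense = np.asarray(X.todense()).astype(bool)
        idx = np.array([_tree_predict_one(model.payload, row) for row in dense])
    elif model.kind == "svm":
        idx = model.payload.predict(X.astype(np.float64))
    else:
        raise ValueError(f"unknown classifier kind {model.kind!r}")
    return [model.classes[i] for i in idx]


def _check_dims(model: ClassifierModel, matrix: MatrixLike) -> sp.csr_matrix:
    X = _as_array(matrix)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension mismatch: model expects {model.n_features}, got {X.shape[1]}"
        )
    return X


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: ClassifierModel, path: str | Path) -> None:
    """Save a model: documented JSON for naive Bayes and the tree, the
    delegated solver's joblib serialization for the SVM."""
    path = Path(path)
    if model.kind == "svm":
        joblib.dump(
            {
                "kind": model.kind,
                "classes": model.classes,
                "n_features": model.n_features,
                "payload": model.payload,
                "provenance": model.provenance,
            },
            path,
        )
        return
    if model.kind == "naive_bayes":
        payload = {k: v.tolist() for k, v in model.payload.items()}
    else:
        payload = model.payload
    doc = {
        "kind": model.kind,
        "classes": model.classes,
        "n_features": model.n_features,
        "payload": payload,
        "provenance": model.provenance,
    }
    path.write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError):
        doc = joblib.load(path)
    if doc["kind"] == "naive_bayes":
        doc["payload"] = {k: np.asarray(v) for k, v in doc["payload"].items()}
    return ClassifierModel(
        kind=doc["kind"],
        classes=list(doc["classes"]),
        n_features=int(doc["n_features"]),
        payload=doc["payload"],
        provenance=dict(doc.get("provenance", {})),
    )
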