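"""Information-gain feature scoring and threshold reduction.

For a binary feature t over labeled documents, the information gain is the
reduction in class entropy from observing t's presence/absence:

    G(t) = - sum_i P(c_i) log P(c_i)
           + P(t)    sum_i P(c_i | t)    log P(c_i | t)
           + P(t^-)  sum_i P(c_i | t^-)  log P(c_i | t^-)

with maximum-likelihood (count-ratio) probabilities, the convention
0 * log 0 = 0, and logs in base 2 (gains in bits), so
0 <= G(t) <= log2(m) for m classes.  Features are retained when their gain
is strictly greater than a threshold (default 0.0025 bits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .features import FeatureDescriptor, FeatureMatrix

__all__ = [
    "IGScores",
    "information_gain",
    "information_gain_matrix",
    "score_all",
    "select_features",
    "export_scores",
]


@dataclass
class IGScores:
    """Per-descriptor information gain plus the sizes it was computed from."""

    descriptors: list[FeatureDescriptor]
    gains: np.ndarray
    n_classes: int
    n_documents: int
    log_base: float = 2.0

    def as_dict(self) -> dict[FeatureDescriptor, float]:
        return {d: float(g) for d, g in zip(self.descriptors, self.gains)}


def _xlogx(p: np.ndarray, base: float) -> np.ndarray:
    """p * log(p) with the 0 * log 0 = 0 convention, elementwise."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * (np.log(p[nz]) / np.log(base))
    return out


def information_gain(
    presence: Sequence[int] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    base: float = 2.0,
) -> float:
    """Information gain of one binary feature column (bits by default)."""
    presence = np.asarray(presence)
    labels = np.asarray(labels)
    if presence.shape != labels.shape:
        raise ValueError("presence and labels must have equal length")
    if presence.size < 1:
        raise ValueError("need at least one document")
    col = (presence != 0).astype(np.uint8).reshape(-1, 1)
    return float(information_gain_matrix(col, labels, base=base)[0])


def information_gain_matrix(
    X: sp.spmatrix | np.ndarray,
    labels: np.ndarray,
    base: float = 2.0,
) -> np.ndarray:
    """Vectorized gain over every column of a binary document x feature
    matrix.  Returns one gain per column."""
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < 1:
        raise ValueError("need at least one document")
    classes, y = np.unique(labels, return_inverse=True)
    m = classes.shape[0]
    # class indicator: m x n
    Y = np.zeros((m, n))
    Y[y, np.arange(n)] = 1.0

    if sp.issparse(X):
        Xb = X.tocsc().astype(bool).astype(float)
        joint_present = np.asarray((Y @ Xb))  # m x F: count(class i, t present)
    else:
        Xb = (np.asarray(X) != 0).astype(float)
        joint_present = Y @ Xb
    class_counts = Y.sum(axis=1)  # m
    joint_absent = class_counts[:, None] - joint_present

    p_class = class_counts / n
    n_present = joint_present.sum(axis=0)  # F
    n_absent = n - n_present
    prior_entropy = -_xlogx(p_class, base).sum()

    with np.errstate(invalid="ignore", divide="ignore"):
        cond_present = np.where(n_present > 0, joint_present / np.maximum(n_present, 1), 0.0)
        cond_absent = np.where(n_absent > 0, joint_absent / np.maximum(n_absent, 1), 0.0)
    term_present = (n_present / n) * _xlogx(cond_present, base).sum(axis=0)
    term_absent = (n_absent / n) * _xlogx(cond_absent, base).sum(axis=0)

    gains = prior_entropy + term_present + term_absent
    # clip tiny negative round-off; gains are mathematically >= 0
    return np.maximum(gains, 0.0)


def score_all(matrix: FeatureMatrix, labels: Sequence, base: float = 2.0) -> IGScores:
    """Information gain of every feature in a matrix.

    ``labels`` may be class strings or indices; every row must be labeled.
    """
    labels = list(labels)
    if len(labels) != matrix.shape[0]:
        raise ValueError("labels length must equal number of rows")
    if any(lab is None for lab in labels):
        raise ValueError("all rows must be labeled for information-gain scoring")
    _, y = np.unique(np.asarray(labels, dtype=object), return_inverse=True)
    gains = information_gain_matrix(matrix.matrix, y, base=base)
    return IGScores(
        descriptors=list(matrix.space.descriptors),
        gains=gains,
        n_classes=int(np.unique(y).shape[0]),
        n_documents=len(labels),
        log_base=base,
    )


def select_features(
    scores: IGScores, threshold: float = 0.0025
) -> list[FeatureDescriptor]:
    """Descriptors whose gain is strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("IG threshold must be >= 0")
    return [d for d, g in zip(scores.descriptors, scores.gains) if g > threshold]


def export_scores(scores: IGScores, path: str | Path) -> None:
    """TSV of (descriptor, gain), sorted by descending gain then name."""
    order = sorted(
        range(len(scores.descriptors)),
        key=lambda i: (-scores.gains[i], str(scores.descriptors[i])),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature\tinformation_gain\n")
        for i in order:
            fh.write(f"{scores.descriptors[i]}\t{scores.gains[i]:.12g}\n")
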