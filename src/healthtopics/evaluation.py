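"""Evaluation protocol: confusion-matrix metrics, stratified tenfold
cross-validation, repeated runs, paired t-tests, and frequency-threshold
sweeps.

Fold aggregation pools the test predictions of all folds into a single
confusion matrix (per-fold metrics are kept as well, for the t-tests).
The "Average" row uses macro (unweighted) averaging over classes.  Paired
t-tests are one-sided for mean(b - a) > 0, paired across repetitions by
shared fold seeds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.stats
import sklearn.metrics
from sklearn.model_selection import KFold, StratifiedKFold

from .corpus import LabeledCorpus
from .features import assemble_feature_space, preprocess_corpus, vectorize
from .lexicons import DomainLexicon, SentimentLexicon
from .preprocess import default_stoplist
from . import classifiers as _clf

__all__ = [
    "ConfusionMatrix",
    "EvaluationReport",
    "confusion_matrix",
    "compute_metrics",
    "cross_validate",
    "repeated_cv",
    "paired_t_test",
    "sweep_frequency_threshold",
]


@dataclass
class ConfusionMatrix:
    """m x m counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_tp_fp_fn_tn(self) -> dict:
        out = {}
        total = self.total
        for i, lab in enumerate(self.class_order):
            tp = int(self.counts[i, i])
            fp = int(self.counts[:, i].sum() - tp)
            fn = int(self.counts[i, :].sum() - tp)
            out[lab] = {"TP": tp, "FP": fp, "FN": fn, "TN": total - tp - fp - fn}
        return out


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, class_order: Sequence
) -> ConfusionMatrix:
    """Tally predictions into an m x m matrix in the given class order."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences must have equal length")
    known = set(class_order)
    for lab in true_labels + predicted_labels:
        if lab not in known:
            raise ValueError(f"label {lab!r} not in class order")
    if not true_labels:
        counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    else:
        counts = sklearn.metrics.confusion_matrix(
            true_labels, predicted_labels, labels=list(class_order)
        )
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def compute_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, per-class precision/recall/F and their macro averages.

    Zero-denominator convention: precision (recall) is 0 when the class is
    never predicted (never true); F is 0 when P + R = 0.
    """
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    accuracy = float(np.trace(cm.counts)) / total
    per_class = {}
    for lab, c in cm.per_class_tp_fp_fn_tn().items():
        p = c["TP"] / (c["TP"] + c["FP"]) if (c["TP"] + c["FP"]) > 0 else 0.0
        r = c["TP"] / (c["TP"] + c["FN"]) if (c["TP"] + c["FN"]) > 0 else 0.0
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        per_class[lab] = {"precision": p, "recall": r, "f1": f}
    macro = {
        key: float(np.mean([v[key] for v in per_class.values()]))
        for key in ("precision", "recall", "f1")
    }
    return {"accuracy": accuracy, "per_class": per_class, "macro": macro}


@dataclass
class EvaluationReport:
    """Pooled confusion matrix, its metrics, per-fold traces, and the
    configuration that produced them."""

    confusion: ConfusionMatrix
    metrics: dict
    per_fold: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]

    @property
    def macro_f(self) -> float:
        return self.metrics["macro"]["f1"]

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "class_order": self.confusion.class_order,
            "confusion": self.confusion.counts.tolist(),
            "metrics": self.metrics,
            "per_fold": self.per_fold,
        }

    def per_class_table(self) -> str:
        """TSV table: topic x precision/recall/F plus the macro Average row."""
        lines = ["topic\tprecision\trecall\tf_measure"]
        for lab, v in self.metrics["per_class"].items():
            lines.append(f"{lab}\t{v['precision']:.4f}\t{v['recall']:.4f}\t{v['f1']:.4f}")
        m = self.metrics["macro"]
        lines.append(f"Average\t{m['precision']:.4f}\t{m['recall']:.4f}\t{m['f1']:.4f}")
        return "\n".join(lines) + "\n"


_TRAINERS = {
    "naive_bayes": _clf.train_naive_bayes,
    "nb": _clf.train_naive_bayes,
    "decision_tree": _clf.train_decision_tree,
    "tree": _clf.train_decision_tree,
    "svm": _clf.train_svm,
}


def _train(kind: str, matrix, labels, class_order, params: Optional[dict]):
    if kind not in _TRAINERS:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return _TRAINERS[kind](matrix, labels, class_order=class_order, **(params or {}))


def cross_validate(
    corpus: LabeledCorpus,
    recipe: str = "FS1",
    classifier_kind: str = "naive_bayes",
    params: Optional[dict] = None,
    k: int = 10,
    seed: int = 0,
    stoplist: Optional[set] = None,
    domain_lexicon: Optional[DomainLexicon] = None,
    sentiment_lexicon: Optional[SentimentLexicon] = None,
    freq_threshold: int = 20,
    subjectivity_threshold: float = 0.5,
    ig_threshold: float = 0.0025,
    paper_mode: bool = False,
    stratified: bool = True,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of one configuration.

    Each fold trains on (k-1)/k of the data and tests on the rest.  The
    feature space (and the FS4 information-gain reduction) is rebuilt on
    the training portion of every fold, so no test information leaks into
    feature selection; ``paper_mode=True`` instead builds them once on the
    full corpus.  Folds are seeded and per-class fold sizes differ by at
    most one.  The report pools all test predictions into one confusion
    matrix and keeps per-fold metrics.
    """
    if stoplist is None:
        stoplist = default_stoplist()
    labels = corpus.labels
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires a fully labeled corpus")
    class_counts = Counter(labels)
    for lab in corpus.label_set:
        if class_counts[lab] < k:
            raise ValueError(
                f"class {lab!r} has {class_counts[lab]} members, fewer than k={k} folds"
            )

    token_seqs = preprocess_corpus(corpus.messages, stoplist)
    y = np.asarray(labels, dtype=object)

    space_kwargs = dict(
        domain_lexicon=domain_lexicon,
        sentiment_lexicon=sentiment_lexicon,
        recipe=recipe,
        freq_threshold=freq_threshold,
        subjectivity_threshold=subjectivity_threshold,
        ig_threshold=ig_threshold,
    )
    full_space = None
    if paper_mode:
        full_space = assemble_feature_space(
            corpus, stoplist, token_seqs=token_seqs, **space_kwargs
        )

    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros(len(corpus))

    pooled_true: list = []
    pooled_pred: list = []
    per_fold = []
    for fold_no, (train_idx, test_idx) in enumerate(splitter.split(dummy, y)):
        train_corpus = corpus.subset(train_idx)
        train_ts = [token_seqs[i] for i in train_idx]
        test_ts = [token_seqs[i] for i in test_idx]
        space = full_space if paper_mode else assemble_feature_space(
            train_corpus, stoplist, token_seqs=train_ts, **space_kwargs
        )
        test_msgs = [corpus.messages[i] for i in test_idx]
        true = [y[i] for i in test_idx]
        if len(space) == 0:
            # degenerate space: majority-class prediction from the training split
            maj = _majority_label(train_corpus)
            pred = [maj] * len(test_idx)
        else:
            Xtr = vectorize(
                train_corpus.messages, space, stoplist,
                domain_lexicon=domain_lexicon, sentiment_lexicon=sentiment_lexicon,
                token_seqs=train_ts,
            )
            Xte = vectorize(
                test_msgs, space, stoplist,
                domain_lexicon=domain_lexicon, sentiment_lexicon=sentiment_lexicon,
                token_seqs=test_ts,
            )
            model = _train(classifier_kind, Xtr, train_corpus.labels, corpus.label_set, params)
            pred = _clf.predict(model, Xte)
        pooled_true.extend(true)
        pooled_pred.extend(pred)
        fold_cm = confusion_matrix(true, pred, corpus.label_set)
        per_fold.append(
            {
                "fold": fold_no,
                "test_indices": [int(i) for i in test_idx],
                "metrics": compute_metrics(fold_cm),
            }
        )

    cm = confusion_matrix(pooled_true, pooled_pred, corpus.label_set)
    config = {
        "recipe": recipe,
        "classifier": classifier_kind,
        "params": params or {},
        "k": k,
        "seed": seed,
        "freq_threshold": freq_threshold,
        "subjectivity_threshold": subjectivity_threshold,
        "ig_threshold": ig_threshold,
        "paper_mode": paper_mode,
        "stratified": stratified,
    }
    return EvaluationReport(
        confusion=cm, metrics=compute_metrics(cm), per_fold=per_fold, config=config
    )


def _majority_label(corpus: LabeledCorpus):
    counts = Counter(corpus.labels)
    best = max(counts.values())
    for lab in corpus.label_set:  # ties to first class in class order
        if counts[lab] == best:
            return lab
    raise ValueError("empty corpus")


def repeated_cv(
    corpus: LabeledCorpus,
    configs: Sequence[dict],
    repetitions: int = 10,
    seed: int = 0,
    k: int = 10,
    **shared_kwargs,
) -> dict:
    """Repeat k-fold CV ``repetitions`` times for every configuration.

    Each configuration dict may set ``recipe``, ``classifier_kind``,
    ``params`` and threshold overrides; remaining keyword arguments
    (stoplist, lexicons, ...) are shared.  Repetition r of every config
    uses the same fold seed, giving a paired design for the t-tests.
    Returns ``{"fold_seeds": [...], "results": [{"config":...,
    "accuracy": [...], "macro_f": [...]}, ...]}``.
    """
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2")
    rng = np.random.default_rng(seed)
    fold_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=repetitions)]
    results = []
    for config in configs:
        cfg = dict(config)
        acc, macro_f = [], []
        for r in range(repetitions):
            report = cross_validate(
                corpus, k=k, seed=fold_seeds[r], **cfg, **shared_kwargs
            )
            acc.append(report.accuracy)
            macro_f.append(report.macro_f)
        results.append({"config": cfg, "accuracy": acc, "macro_f": macro_f})
    return {"fold_seeds": fold_seeds, "results": results}


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Paired t-test, one-sided for mean(b - a) > 0.

    Returns (t, p) with t = mean(d) / (sd(d) / sqrt(n)), d = b - a, sample
    standard deviation (n - 1 denominator), and p from Student's t with
    n - 1 degrees of freedom.  Degenerate cases: all differences zero ->
    (0, 0.5); zero spread with nonzero mean -> (+/-inf, 0 or 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = b - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 0.5
        t = float("inf") if mean > 0 else float("-inf")
        return t, 0.0 if mean > 0 else 1.0
    t = mean / (sd / np.sqrt(n))
    p = float(scipy.stats.t.sf(t, df=n - 1))
    return float(t), p


def sweep_frequency_threshold(
    corpus: LabeledCorpus,
    thresholds: Sequence[int],
    classifier_kind: str = "naive_bayes",
    k: int = 10,
    seed: int = 0,
    **kwargs,
) -> list[dict]:
    """FS1 cross-validation accuracy at each n-gram frequency threshold."""
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    out = []
    for thr in thresholds:
        report = cross_validate(
            corpus,
            recipe="FS1",
            classifier_kind=classifier_kind,
            k=k,
            seed=seed,
            freq_threshold=thr,
            **kwargs,
        )
        out.append({"threshold": thr, "accuracy": report.accuracy, "macro_f": report.macro_f})
    return out
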