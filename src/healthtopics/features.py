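"""Feature extraction and feature-set assembly (FS1-FS4).

Three feature families are extracted from each message:

* ``ngram`` -- word n-grams (n <= 3) over the stemmed, stop-filtered
  tokens, retained when their corpus-wide occurrence count reaches a
  frequency threshold (default 20);
* ``domain`` -- medical terms matched against the domain lexicon by greedy
  left-to-right longest match over the raw lowercased tokens;
* ``sentiment`` -- high-subjectivity lemmas (subjectivity > 0.5) present
  among the raw tokens.

Feature sets are incremental: FS1 = n-grams; FS2 = FS1 + domain terms;
FS3 = FS2 + sentiment terms; FS4 = FS3 with the n-gram family reduced by
information gain (gain strictly > a threshold, default 0.0025).  Feature
values are binary presence indicators; families are namespaced so a string
that is both a frequent unigram and a lexicon term yields two distinct
columns.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .corpus import LabeledCorpus, Message
from .lexicons import DomainLexicon, SentimentLexicon, sentiment_feature_terms
from .preprocess import TokenSequence, preprocess_message

__all__ = [
    "FeatureDescriptor",
    "FeatureSpace",
    "FeatureMatrix",
    "extract_ngrams",
    "build_ngram_vocabulary",
    "extract_domain_features",
    "extract_sentiment_features",
    "assemble_feature_space",
    "vectorize",
    "export_matrix",
    "import_matrix",
    "preprocess_corpus",
]

RECIPES = ("FS1", "FS2", "FS3", "FS4")

#: Fixed namespace ordering used when sorting a feature space.
_NAMESPACE_ORDER = {"ngram": 0, "domain": 1, "sentiment": 2}


@dataclass(frozen=True, order=False)
class FeatureDescriptor:
    """One feature: its family, key string, and n-gram order (1 otherwise)."""

    namespace: str
    key: str
    order: int = 1

    def __post_init__(self) -> None:
        if self.namespace not in _NAMESPACE_ORDER:
            raise ValueError(f"unknown feature namespace: {self.namespace!r}")
        if not (1 <= self.order <= 3):
            raise ValueError("feature order must be in 1..3")

    @property
    def sort_key(self) -> tuple[int, str]:
        return (_NAMESPACE_ORDER[self.namespace], self.key)

    def __str__(self) -> str:
        return f"{self.namespace}:{self.key}"


@dataclass
class FeatureSpace:
    """Ordered feature descriptors plus the recipe and thresholds that
    built them (provenance)."""

    descriptors: list[FeatureDescriptor]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len({(d.namespace, d.key) for d in self.descriptors}) != len(self.descriptors):
            raise ValueError("duplicate (namespace, key) in feature space")

    def __len__(self) -> int:
        return len(self.descriptors)

    def index(self) -> dict[tuple[str, str], int]:
        return {(d.namespace, d.key): i for i, d in enumerate(self.descriptors)}

    def by_namespace(self, namespace: str) -> list[FeatureDescriptor]:
        return [d for d in self.descriptors if d.namespace == namespace]


@dataclass
class FeatureMatrix:
    """Sparse document x feature matrix (binary by default) plus row ids."""

    matrix: sp.csr_matrix
    space: FeatureSpace
    ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.ids), len(self.space)):
            raise ValueError("matrix dimensions do not match ids x feature space")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def extract_ngrams(tokens: Sequence[str], n_max: int = 3) -> Counter:
    """All contiguous n-grams for n = 1..n_max, space-joined, with
    multiplicity.  A token list of length L >= n_max yields
    sum_n (L - n + 1) n-grams."""
    if not (1 <= n_max <= 3):
        raise ValueError("n_max must be in 1..3")
    counts: Counter = Counter()
    L = len(tokens)
    for n in range(1, n_max + 1):
        for i in range(L - n + 1):
            counts[" ".join(tokens[i : i + n])] += 1
    return counts


def preprocess_corpus(
    messages: Iterable[Message], stoplist: set[str]
) -> list[TokenSequence]:
    """Preprocess every message once; downstream stages reuse the result."""
    return [preprocess_message(m, stoplist) for m in messages]


def build_ngram_vocabulary(
    corpus: LabeledCorpus | Sequence[Message],
    stoplist: set[str],
    freq_threshold: int = 20,
    n_max: int = 3,
    count_mode: str = "total",
    token_seqs: Optional[Sequence[TokenSequence]] = None,
) -> list[FeatureDescriptor]:
    """n-grams whose corpus frequency is >= ``freq_threshold``.

    ``count_mode="total"`` (default) counts every occurrence; ``"document"``
    counts each document once.  Ordering is deterministic: by n-gram order,
    then key.
    """
    if freq_threshold < 1:
        raise ValueError("freq_threshold must be >= 1")
    if count_mode not in ("total", "document"):
        raise ValueError("count_mode must be 'total' or 'document'")
    messages = list(corpus)
    if token_seqs is None:
        token_seqs = preprocess_corpus(messages, stoplist)
    counts: Counter = Counter()
    for ts in token_seqs:
        grams = extract_ngrams(ts.stemmed_tokens, n_max=n_max)
        if count_mode == "document":
            counts.update(set(grams))
        else:
            counts.update(grams)
    kept = sorted(g for g, c in counts.items() if c >= freq_threshold)
    return [FeatureDescriptor("ngram", g, order=g.count(" ") + 1) for g in kept]


def extract_domain_features(
    raw_tokens: Sequence[str], lexicon: DomainLexicon
) -> set[str]:
    """Greedy left-to-right longest-match of lexicon phrases (<= 3 words)
    over the raw lowercased tokens; matched spans do not overlap."""
    matched: set[str] = set()
    max_len = min(lexicon.max_phrase_len, 3)
    i = 0
    L = len(raw_tokens)
    while i < L:
        hit = None
        for n in range(min(max_len, L - i), 0, -1):
            phrase = " ".join(raw_tokens[i : i + n])
            if phrase in lexicon:
                hit = (phrase, n)
                break
        if hit is not None:
            matched.add(hit[0])
            i += hit[1]
        else:
            i += 1
    return matched


def extract_sentiment_features(
    raw_tokens: Sequence[str], sentiment_terms: set[str]
) -> set[str]:
    """Raw lowercased tokens that are qualifying sentiment lemmas."""
    return set(raw_tokens) & sentiment_terms


def assemble_feature_space(
    corpus: LabeledCorpus,
    stoplist: set[str],
    domain_lexicon: Optional[DomainLexicon] = None,
    sentiment_lexicon: Optional[SentimentLexicon] = None,
    recipe: str = "FS1",
    freq_threshold: int = 20,
    subjectivity_threshold: float = 0.5,
    ig_threshold: float = 0.0025,
    n_max: int = 3,
    count_mode: str = "total",
    token_seqs: Optional[Sequence[TokenSequence]] = None,
) -> FeatureSpace:
    """Build the feature space for one of the incremental recipes FS1-FS4.

    Domain and sentiment descriptors are admitted on any observed
    occurrence (no frequency threshold); FS4 reduces the n-gram family
    only, keeping n-grams with information gain strictly greater than
    ``ig_threshold`` (computed from the corpus labels, which must all be
    present).
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; expected one of {RECIPES}")
    if recipe in ("FS2", "FS3", "FS4") and domain_lexicon is None:
        raise ValueError(f"recipe {recipe} requires a domain lexicon")
    if recipe in ("FS3", "FS4") and sentiment_lexicon is None:
        raise ValueError(f"recipe {recipe} requires a sentiment lexicon")

    messages = list(corpus)
    if token_seqs is None:
        token_seqs = preprocess_corpus(messages, stoplist)

    ngram_desc = build_ngram_vocabulary(
        messages,
        stoplist,
        freq_threshold=freq_threshold,
        n_max=n_max,
        count_mode=count_mode,
        token_seqs=token_seqs,
    )

    domain_desc: list[FeatureDescriptor] = []
    sentiment_desc: list[FeatureDescriptor] = []
    if recipe in ("FS2", "FS3", "FS4"):
        observed: set[str] = set()
        for ts in token_seqs:
            observed |= extract_domain_features(ts.raw_tokens, domain_lexicon)
        domain_desc = [
            FeatureDescriptor("domain", t, order=1) for t in sorted(observed)
        ]
    if recipe in ("FS3", "FS4"):
        terms = sentiment_feature_terms(sentiment_lexicon, threshold=subjectivity_threshold)
        observed_s: set[str] = set()
        for ts in token_seqs:
            observed_s |= extract_sentiment_features(ts.raw_tokens, terms)
        sentiment_desc = [
            FeatureDescriptor("sentiment", t, order=1) for t in sorted(observed_s)
        ]

    if recipe == "FS4":
        if any(m.label is None for m in messages):
            raise ValueError("FS4 requires every message to be labeled (IG needs labels)")
        ngram_desc = _ig_reduce_ngrams(
            ngram_desc, token_seqs, corpus, n_max=n_max, ig_threshold=ig_threshold
        )

    descriptors = sorted(ngram_desc + domain_desc + sentiment_desc, key=lambda d: d.sort_key)
    provenance = {
        "recipe": recipe,
        "freq_threshold": freq_threshold,
        "subjectivity_threshold": subjectivity_threshold,
        "ig_threshold": ig_threshold if recipe == "FS4" else None,
        "n_max": n_max,
        "count_mode": count_mode,
    }
    return FeatureSpace(descriptors=descriptors, provenance=provenance)


def _ig_reduce_ngrams(
    ngram_desc: list[FeatureDescriptor],
    token_seqs: Sequence[TokenSequence],
    corpus: LabeledCorpus,
    n_max: int,
    ig_threshold: float,
) -> list[FeatureDescriptor]:
    from .selection import information_gain_matrix

    if not ngram_desc:
        return []
    presence = _ngram_presence(ngram_desc, token_seqs, n_max)
    labels = np.asarray(corpus.class_indices())
    gains = information_gain_matrix(presence, labels)
    return [d for d, g in zip(ngram_desc, gains) if g > ig_threshold]


def _ngram_presence(
    ngram_desc: Sequence[FeatureDescriptor],
    token_seqs: Sequence[TokenSequence],
    n_max: int,
) -> sp.csr_matrix:
    col = {d.key: j for j, d in enumerate(ngram_desc)}
    rows, cols = [], []
    for i, ts in enumerate(token_seqs):
        for g in extract_ngrams(ts.stemmed_tokens, n_max=n_max):
            j = col.get(g)
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows), dtype=np.uint8)
    mat = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(token_seqs), len(ngram_desc)), dtype=np.uint8
    ).tocsr()
    mat.data[:] = 1  # presence, not counts (duplicates summed by coo->csr)
    return mat


def vectorize(
    messages: Iterable[Message] | LabeledCorpus,
    space: FeatureSpace,
    stoplist: set[str],
    domain_lexicon: Optional[DomainLexicon] = None,
    sentiment_lexicon: Optional[SentimentLexicon] = None,
    binary: bool = True,
    token_seqs: Optional[Sequence[TokenSequence]] = None,
) -> FeatureMatrix:
    """Binary presence matrix of the messages in the given feature space.

    n-gram columns are matched over stemmed tokens; domain columns over
    raw tokens via the greedy lexicon matcher; sentiment columns over raw
    tokens by membership.  ``binary=False`` records n-gram occurrence
    counts instead of presence (domain/sentiment stay presence-valued).
    """
    msgs = list(messages)
    if token_seqs is None:
        token_seqs = preprocess_corpus(msgs, stoplist)
    if any(d.namespace == "domain" for d in space.descriptors) and domain_lexicon is None:
        raise ValueError("feature space has domain features but no domain lexicon given")

    index = space.index()
    n_max = space.provenance.get("n_max", 3)
    sentiment_keys = {d.key for d in space.descriptors if d.namespace == "sentiment"}

    rows, cols, vals = [], [], []
    for i, ts in enumerate(token_seqs):
        grams = extract_ngrams(ts.stemmed_tokens, n_max=n_max)
        for g, c in grams.items():
            j = index.get(("ngram", g))
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(1 if binary else c)
        if domain_lexicon is not None:
            for t in extract_domain_features(ts.raw_tokens, domain_lexicon):
                j = index.get(("domain", t))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(1)
        if sentiment_keys:
            for t in set(ts.raw_tokens) & sentiment_keys:
                j = index.get(("sentiment", t))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    vals.append(1)

    dtype = np.uint8 if binary else np.int64
    mat = sp.coo_matrix(
        (np.asarray(vals, dtype=dtype), (rows, cols)),
        shape=(len(msgs), len(space)),
        dtype=dtype,
    ).tocsr()
    return FeatureMatrix(matrix=mat, space=space, ids=[m.id for m in msgs])


def export_matrix(fm: FeatureMatrix, prefix: str | Path) -> None:
    """Write <prefix>.mtx (MatrixMarket), <prefix>.features.txt
    (namespace:key per line) and <prefix>.ids.txt (row ids)."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", fm.matrix)
    with open(str(prefix) + ".features.txt", "w", encoding="utf-8") as fh:
        for d in fm.space.descriptors:
            fh.write(f"{d.namespace}:{d.key}\n")
    with open(str(prefix) + ".ids.txt", "w", encoding="utf-8") as fh:
        for i in fm.ids:
            fh.write(i + "\n")


def import_matrix(prefix: str | Path) -> FeatureMatrix:
    """Inverse of :func:`export_matrix` (provenance is not recovered)."""
    prefix = Path(prefix)
    mat = sp.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    descriptors = []
    with open(str(prefix) + ".features.txt", encoding="utf-8") as fh:
        for line in fh:
            ns, _, key = line.rstrip("\n").partition(":")
            descriptors.append(
                FeatureDescriptor(ns, key, order=key.count(" ") + 1 if ns == "ngram" else 1)
            )
    with open(str(prefix) + ".ids.txt", encoding="utf-8") as fh:
        ids = [line.rstrip("\n") for line in fh]
    space = FeatureSpace(descriptors=descriptors, provenance={"recipe": "imported"})
    return FeatureMatrix(matrix=mat, space=space, ids=ids)
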