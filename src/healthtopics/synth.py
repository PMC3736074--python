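"""Synthetic labeled corpora with the statistical structure the topic
classifier assumes, plus matching mini-lexicons and a Bayes-optimal
reference oracle.

The generator emulates a three-board health forum: message classes
("treatment" / "emotional" / "survivorship") are drawn with the imbalance
of the emulated corpus (1224 : 991 : 1826 out of 4041), message length is
class-conditional Poisson, and tokens are emitted i.i.d. from a per-class
mixture of

* common function words (removed by the stop list downstream),
* a shared background vocabulary (Zipf weighted, no class signal),
* class-signature words and atomic multiword signature phrases
  (the n-gram signal),
* class-specific medical domain terms (highest rate in the
  treatment-like class), and
* class-specific high-subjectivity sentiment lemmas (highest rate in the
  emotional-support-like class).

All non-shared vocabularies are disjoint across classes and families, so
the emission events are recoverable from the token stream and the
true-parameter (Bayes-optimal) classifier over the event sequence is
exact.  Every draw flows from one seed; a fixed seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.stats
import yaml

from .corpus import LabeledCorpus, Message
from .lexicons import DomainLexicon, SentimentLexicon, Sense

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_lexicons",
    "bayes_optimal_accuracy",
    "write_domain_lexicon",
    "write_sentiment_lexicon",
    "default_config",
    "strong_signature_config",
    "domain_signal_config",
    "no_signal_config",
]

_FUNCTION_WORDS = (
    "the", "and", "of", "to", "i", "my", "was", "it", "for", "that",
    "with", "have", "but", "so", "on", "in", "all", "this", "are", "be",
)

#: Semantic-type codes cycled over generated domain terms.
_DOMAIN_CODES = ("Topp", "Phsu", "Dsyn", "Sosy", "Diap", "Neop", "Orch", "Bpoc", "Patf", "Mobd")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the emulated forum: 4041 messages at class
    proportions 1224:991:1826, treatment-heavy domain-term usage and
    emotional-support-heavy sentiment-term usage.  ``signature_weight``
    is the per-event probability of emitting a class-signature item;
    ``domain_rates`` / ``sentiment_rates`` are per-class per-event
    injection probabilities.
    """

    n_messages: int = 4041
    class_names: tuple[str, ...] = ("treatment", "emotional", "survivorship")
    class_proportions: tuple[float, ...] = (1224 / 4041, 991 / 4041, 1826 / 4041)
    length_means: tuple[float, ...] = (45.0, 28.0, 50.0)
    shared_vocab_size: int = 600
    signature_vocab_size: int = 40
    signature_phrases: int = 5
    signature_weight: float = 0.15
    domain_terms_per_class: int = 40
    domain_bigram_fraction: float = 0.2
    domain_rates: tuple[float, ...] = (0.10, 0.02, 0.05)
    sentiment_terms_per_class: int = 25
    sentiment_rates: tuple[float, ...] = (0.02, 0.10, 0.05)
    function_word_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.class_names)
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (m,) or np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError("class_proportions must be a simplex vector over the classes")
        for rates in (self.domain_rates, self.sentiment_rates):
            if len(rates) != m or any(not (0.0 <= r <= 1.0) for r in rates):
                raise ValueError("per-class rates must lie in [0, 1]")
        if not (0.0 <= self.signature_weight <= 1.0):
            raise ValueError("signature_weight must lie in [0, 1]")
        for c in range(m):
            total = (
                self.function_word_rate
                + self.signature_weight
                + self.domain_rates[c]
                + self.sentiment_rates[c]
            )
            if total > 1.0 + 1e-9:
                raise ValueError(f"mixture weights exceed 1 for class {self.class_names[c]!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("class_names", "class_proportions", "length_means", "domain_rates", "sentiment_rates"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yml", ".yaml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


@dataclass
class GroundTruth:
    """Generative parameters for oracle computations."""

    class_names: tuple[str, ...]
    priors: np.ndarray
    length_means: np.ndarray
    #: per class: list of emission events, each a tuple of tokens
    events: list
    #: per class: emission probability per event (same order as events)
    event_probs: list
    domain_terms: dict = field(default_factory=dict)
    sentiment_terms: dict = field(default_factory=dict)


def _class_prefix(name: str) -> str:
    return "".join(ch for ch in name.lower() if ch.isalpha())[:4]


def _build_model(config: SynthConfig) -> GroundTruth:
    """The per-class emission distributions implied by a config."""
    m = len(config.class_names)
    shared = [f"word{i:04d}" for i in range(config.shared_vocab_size)]
    shared_w = 1.0 / (np.arange(config.shared_vocab_size) + 2.0)  # Zipf-ish tail
    shared_w /= shared_w.sum()
    func_w = np.full(len(_FUNCTION_WORDS), 1.0 / len(_FUNCTION_WORDS))

    domain_terms: dict[str, list[str]] = {}
    sentiment_terms: dict[str, list[str]] = {}
    events_per_class = []
    probs_per_class = []
    for c, name in enumerate(config.class_names):
        pfx = _class_prefix(name)
        sig_items: list[tuple[str, ...]] = [
            (f"{pfx}sig{i:03d}",) for i in range(config.signature_vocab_size)
        ]
        sig_items += [
            (f"{pfx}phr{i:02d}a", f"{pfx}phr{i:02d}b") for i in range(config.signature_phrases)
        ]
        sig_w = 1.0 / (np.arange(len(sig_items)) + 1.0)  # Zipf within the signature
        sig_w = sig_w / sig_w.sum() if len(sig_items) else sig_w

        n_bigram = int(round(config.domain_terms_per_class * config.domain_bigram_fraction))
        dom_items: list[tuple[str, ...]] = [
            (f"{pfx}dom{i:03d}",) for i in range(config.domain_terms_per_class - n_bigram)
        ]
        dom_items += [(f"{pfx}dom{i:03d}x", f"{pfx}dom{i:03d}y") for i in range(n_bigram)]
        domain_terms[name] = [" ".join(t) for t in dom_items]

        sen_items: list[tuple[str, ...]] = [
            (f"{pfx}sen{i:03d}",) for i in range(config.sentiment_terms_per_class)
        ]
        sentiment_terms[name] = [t[0] for t in sen_items]

        shared_mass = 1.0 - (
            config.function_word_rate
            + config.signature_weight
            + config.domain_rates[c]
            + config.sentiment_rates[c]
        )
        events: list[tuple[str, ...]] = []
        probs: list[float] = []
        events += [(w,) for w in _FUNCTION_WORDS]
        probs += list(config.function_word_rate * func_w)
        events += [(w,) for w in shared]
        probs += list(shared_mass * shared_w)
        if config.signature_weight > 0 and sig_items:
            events += sig_items
            probs += list(config.signature_weight * sig_w)
        if config.domain_rates[c] > 0 and dom_items:
            events += dom_items
            probs += [config.domain_rates[c] / len(dom_items)] * len(dom_items)
        if config.sentiment_rates[c] > 0 and sen_items:
            events += sen_items
            probs += [config.sentiment_rates[c] / len(sen_items)] * len(sen_items)
        p = np.asarray(probs)
        events_per_class.append(events)
        probs_per_class.append(p / p.sum())

    return GroundTruth(
        class_names=tuple(config.class_names),
        priors=np.asarray(config.class_proportions, dtype=float),
        length_means=np.asarray(config.length_means, dtype=float),
        events=events_per_class,
        event_probs=probs_per_class,
        domain_terms=domain_terms,
        sentiment_terms=sentiment_terms,
    )


def _sample_event_indices(
    truth: GroundTruth, rng: np.random.Generator
) -> tuple[int, np.ndarray]:
    c = int(rng.choice(len(truth.class_names), p=truth.priors))
    n_events = int(rng.poisson(truth.length_means[c]))
    idx = rng.choice(len(truth.events[c]), size=n_events, p=truth.event_probs[c])
    return c, idx


def generate_corpus(config: SynthConfig) -> tuple[LabeledCorpus, GroundTruth]:
    """Draw a labeled corpus; also returns the generative ground truth."""
    truth = _build_model(config)
    rng = np.random.default_rng(config.seed)
    messages = []
    for i in range(config.n_messages):
        c, idx = _sample_event_indices(truth, rng)
        tokens: list[str] = []
        for j in idx:
            tokens.extend(truth.events[c][j])
        messages.append(
            Message(id=f"msg{i:06d}", text=" ".join(tokens), label=truth.class_names[c])
        )
    return LabeledCorpus.from_messages(messages), truth


def generate_lexicons(
    config: SynthConfig, n_distractors: int = 20
) -> tuple[DomainLexicon, SentimentLexicon]:
    """Mini-lexicons matching a config's injected terms.

    Every injected domain term appears with a semantic-type code; every
    injected sentiment lemma has subjectivity 0.75 (> the 0.5 filter);
    ``n_distractors`` extra lemmas have subjectivity exactly 0.5 and are
    excluded by the strict filter.
    """
    truth = _build_model(config)
    entries: dict[str, frozenset[str]] = {}
    i = 0
    for name in config.class_names:
        for term in truth.domain_terms[name]:
            entries[term] = frozenset({_DOMAIN_CODES[i % len(_DOMAIN_CODES)]})
            i += 1
    sent_entries: dict[str, list[Sense]] = {}
    for name in config.class_names:
        for lemma in truth.sentiment_terms[name]:
            sent_entries[lemma] = [Sense(0.5, 0.25, 1)]
    for j in range(n_distractors):
        sent_entries[f"plain{j:03d}"] = [Sense(0.25, 0.25, 1)]
    return DomainLexicon(entries=entries), SentimentLexicon(entries=sent_entries)


def write_domain_lexicon(lexicon: DomainLexicon, path: str | Path) -> None:
    """Emit a term<TAB>code TSV readable by :func:`load_domain_lexicon`."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(lexicon.entries):
            for code in sorted(lexicon.entries[term]):
                fh.write(f"{term}\t{code}\n")


def write_sentiment_lexicon(lexicon: SentimentLexicon, path: str | Path) -> None:
    """Emit a SentiWordNet-3.0 format file readable by
    :func:`load_sentiment_lexicon`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# POS\tID\tPosScore\tNegScore\tSynsetTerms\tGloss\n")
        i = 1
        for lemma in sorted(lexicon.entries):
            for sense in lexicon.entries[lemma]:
                fh.write(
                    f"n\t{i:08d}\t{sense.pos_score:g}\t{sense.neg_score:g}\t"
                    f"{lemma}#{sense.rank}\tsynthetic gloss\n"
                )
                i += 1


def bayes_optimal_accuracy(
    config: SynthConfig, n_mc: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo accuracy of the true-parameter posterior classifier.

    Fresh messages are drawn from the generator; each is scored with the
    exact log-posterior log P(c) + log Poisson(n; mu_c) + sum log p_c(event)
    (events are identifiable because non-shared vocabularies are disjoint).
    Returns (estimate, standard error).
    """
    truth = _build_model(config)
    m = len(truth.class_names)
    # event lookup: token tuple -> per-class emission probability
    lookup: dict[tuple[str, ...], np.ndarray] = {}
    for c in range(m):
        for ev, p in zip(truth.events[c], truth.event_probs[c]):
            lookup.setdefault(ev, np.zeros(m))[c] = p
    log_priors = np.log(truth.priors)

    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_mc):
        c_true, idx = _sample_event_indices(truth, rng)
        n_events = idx.size
        with np.errstate(divide="ignore"):
            scores = log_priors + scipy.stats.poisson.logpmf(n_events, truth.length_means)
            for j in idx:
                scores = scores + np.log(lookup[truth.events[c_true][j]])
        pred = int(np.argmax(scores))  # ties to the first class
        correct += pred == c_true
    acc = correct / n_mc
    se = float(np.sqrt(max(acc * (1 - acc), 1e-12) / n_mc))
    return acc, se


# ---------------------------------------------------------------------------
# Named study conditions
# ---------------------------------------------------------------------------


def default_config(seed: int = 0) -> SynthConfig:
    """The emulated-forum conditions: n = 4041 at proportions 1224:991:1826."""
    return SynthConfig(seed=seed)


def strong_signature_config(n_messages: int = 1000, seed: int = 0) -> SynthConfig:
    """Clearly separated topics: heavy signature emission so the
    Bayes-optimal accuracy is essentially 1."""
    return SynthConfig(
        n_messages=n_messages,
        signature_weight=0.30,
        seed=seed,
    )


def domain_signal_config(n_messages: int = 800, seed: int = 0) -> SynthConfig:
    """Class signal carried almost entirely by many individually-rare
    domain terms: each term's corpus frequency stays below the default
    n-gram threshold (20), so FS1 is nearly signal-free while the FS2
    domain features separate the classes."""
    return SynthConfig(
        n_messages=n_messages,
        length_means=(35.0, 35.0, 35.0),
        signature_weight=0.02,
        domain_terms_per_class=80,
        domain_rates=(0.10, 0.04, 0.07),
        sentiment_rates=(0.0, 0.0, 0.0),
        seed=seed,
    )


def no_signal_config(n_messages: int = 600, seed: int = 0) -> SynthConfig:
    """All classes share one token distribution: no signature, no
    injections, equal lengths.  Bayes-optimal = majority class."""
    return SynthConfig(
        n_messages=n_messages,
        length_means=(35.0, 35.0, 35.0),
        signature_weight=0.0,
        domain_rates=(0.0, 0.0, 0.0),
        sentiment_rates=(0.0, 0.0, 0.0),
        seed=seed,
    )
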