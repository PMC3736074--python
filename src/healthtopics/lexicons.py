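"""Domain (medical-term) and sentiment lexicons.

The domain lexicon maps lowercase 1-3 word phrases to semantic-type codes,
filtered to the 20 health-related UMLS semantic types (Aapp..Topp).  The
sentiment lexicon follows the SentiWordNet-3.0 file layout: each synset
line carries a positivity and negativity score in [0, 1] (objectivity is
the remainder to 1) and a list of ``lemma#rank`` members.  A lemma's
subjectivity is the mean over its senses of positivity + negativity;
sentiment feature terms are the lemmas whose subjectivity strictly exceeds
a threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional

__all__ = [
    "UMLS_SEMANTIC_TYPES",
    "DomainLexicon",
    "SentimentLexicon",
    "Sense",
    "load_domain_lexicon",
    "load_sentiment_lexicon",
    "subjectivity",
    "sentiment_feature_terms",
    "default_domain_lexicon",
    "default_sentiment_lexicon",
]

#: The 20 health-related UMLS semantic-type abbreviations used to filter
#: the domain lexicon (e.g. Dsyn = Disease or syndrome, Sosy = Sign or
#: symptom, Topp = Therapeutic or preventive procedure).
UMLS_SEMANTIC_TYPES: frozenset[str] = frozenset(
    {
        "Aapp",  # Amino acid, peptide, or protein
        "Acab",  # Acquired abnormality
        "Anab",  # Anatomical abnormality
        "Bdsy",  # Body system
        "Blor",  # Body location or region
        "Bmod",  # Biomedical occupation or discipline
        "Bpoc",  # Body part, organ, or organ component
        "Diap",  # Diagnostic procedure
        "Dsyn",  # Disease or syndrome
        "Horm",  # Hormone
        "Imft",  # Immunologic factor
        "Inpo",  # Injury or poisoning
        "Lbpr",  # Laboratory procedure
        "Mobd",  # Mental or behavioral dysfunction
        "Neop",  # Neoplastic process
        "Orch",  # Organic chemical
        "Patf",  # Pathologic function
        "Phsu",  # Pharmacologic substance
        "Sosy",  # Sign or symptom
        "Topp",  # Therapeutic or preventive procedure
    }
)


@dataclass
class DomainLexicon:
    """Map from lowercase term (1-3 word phrase, space-separated) to the
    set of semantic-type codes it carries."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def max_phrase_len(self) -> int:
        if not self.entries:
            return 0
        return max(len(t.split()) for t in self.entries)


class Sense(NamedTuple):
    pos_score: float
    neg_score: float
    rank: int


@dataclass
class SentimentLexicon:
    """Map from lowercase lemma to its per-sense polarity records."""

    entries: dict[str, list[Sense]] = field(default_factory=dict)

    def __contains__(self, lemma: str) -> bool:
        return lemma in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_domain_lexicon(
    path: str | Path,
    allowed_types: Optional[frozenset[str] | set[str]] = None,
    strict: bool = False,
) -> DomainLexicon:
    """Load a term<TAB>code TSV, keeping rows whose code is allowed.

    Rows whose code is outside ``allowed_types`` (default: the 20 UMLS
    codes) are silently dropped, or raise if ``strict``.  A term listed
    under several codes yields one entry with the merged code set, so the
    result is independent of row order.
    """
    allowed = frozenset(allowed_types) if allowed_types is not None else UMLS_SEMANTIC_TYPES
    merged: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{Path(path).name}:{lineno}: expected 'term<TAB>code'")
            term = " ".join(parts[0].strip().lower().split())
            code = parts[1].strip()
            if len(term.split()) > 3:
                raise ValueError(f"{Path(path).name}:{lineno}: term {term!r} longer than 3 words")
            if code not in allowed:
                if strict:
                    raise ValueError(
                        f"{Path(path).name}:{lineno}: unknown semantic-type code {code!r}"
                    )
                continue
            merged.setdefault(term, set()).add(code)
    return DomainLexicon(entries={t: frozenset(c) for t, c in merged.items()})


def load_sentiment_lexicon(path: str | Path) -> SentimentLexicon:
    """Parse a SentiWordNet-3.0 format file.

    Tab-separated columns POS, ID, PosScore, NegScore, SynsetTerms (and an
    optional gloss); ``SynsetTerms`` is a space-separated list of
    ``lemma#rank`` members, each contributing one sense record to that
    lemma.  Lines starting with '#' are ignored.
    """
    entries: dict[str, list[Sense]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{Path(path).name}:{lineno}: expected >= 5 tab-separated columns")
            try:
                pos_score = float(parts[2])
                neg_score = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{Path(path).name}:{lineno}: non-numeric polarity score") from exc
            if not (0.0 <= pos_score <= 1.0 and 0.0 <= neg_score <= 1.0):
                raise ValueError(f"{Path(path).name}:{lineno}: polarity scores must lie in [0, 1]")
            if pos_score + neg_score > 1.0 + 1e-12:
                raise ValueError(
                    f"{Path(path).name}:{lineno}: PosScore + NegScore exceeds 1 "
                    f"({pos_score} + {neg_score})"
                )
            for member in parts[4].split():
                lemma, sep, rank_s = member.rpartition("#")
                if not sep or not lemma:
                    raise ValueError(f"{Path(path).name}:{lineno}: malformed synset term {member!r}")
                try:
                    rank = int(rank_s)
                except ValueError as exc:
                    raise ValueError(
                        f"{Path(path).name}:{lineno}: malformed sense rank in {member!r}"
                    ) from exc
                if rank < 1:
                    raise ValueError(f"{Path(path).name}:{lineno}: sense rank must be >= 1")
                entries.setdefault(lemma.lower(), []).append(Sense(pos_score, neg_score, rank))
    return SentimentLexicon(entries=entries)


def subjectivity(
    lexicon: SentimentLexicon, lemma: str, rank_weighted: bool = False
) -> Optional[float]:
    """Subjectivity of a lemma: 1 - objectivity, aggregated over senses.

    Default aggregation is the unweighted arithmetic mean of per-sense
    (pos + neg); ``rank_weighted`` weights sense s by 1/rank(s) instead.
    Returns None for lemmas not in the lexicon.
    """
    senses = lexicon.entries.get(lemma)
    if not senses:
        return None
    if rank_weighted:
        weights = [1.0 / s.rank for s in senses]
        total = sum(weights)
        return sum(w * (s.pos_score + s.neg_score) for w, s in zip(weights, senses)) / total
    return sum(s.pos_score + s.neg_score for s in senses) / len(senses)


def sentiment_feature_terms(
    lexicon: SentimentLexicon, threshold: float = 0.5, rank_weighted: bool = False
) -> set[str]:
    """Lemmas whose subjectivity is strictly greater than ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("subjectivity threshold must lie in [0, 1]")
    out = set()
    for lemma in lexicon.entries:
        s = subjectivity(lexicon, lemma, rank_weighted=rank_weighted)
        if s is not None and s > threshold:
            out.add(lemma)
    return out


def default_domain_lexicon(strict: bool = True) -> DomainLexicon:
    """The fixture medical mini-lexicon shipped with the package."""
    with resources.as_file(
        resources.files("healthtopics").joinpath("data/domain_lexicon.tsv")
    ) as p:
        return load_domain_lexicon(p, strict=strict)


def default_sentiment_lexicon() -> SentimentLexicon:
    """The fixture sentiment mini-lexicon shipped with the package."""
    with resources.as_file(
        resources.files("healthtopics").joinpath("data/sentiwordnet_mini.txt")
    ) as p:
        return load_sentiment_lexicon(p)
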