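"""Tokenization, stop-word removal, and Porter stemming.

The preprocessing contract is frozen so that feature counts are exactly
reproducible: tokens are maximal runs of letters, digits and apostrophes,
lowercased; stop words are removed before stemming (so bigrams may span a
removed stop word); stems follow the classic Porter (1980) algorithm.

Both token views are kept: lexicon matching (domain and sentiment terms)
operates on the raw lowercased tokens, because lexicon entries are
dictionary forms; n-gram features are built over the stemmed tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .corpus import Message

__all__ = [
    "TokenSequence",
    "tokenize",
    "remove_stopwords",
    "stem",
    "preprocess_message",
    "PorterStemmer",
    "default_stoplist",
    "load_stoplist",
]

_TOKEN_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class TokenSequence:
    """Token views of one message: raw lowercased, and stemmed/stop-filtered."""

    raw_tokens: tuple[str, ...]
    stemmed_tokens: tuple[str, ...]


def tokenize(text: str) -> list[str]:
    """Split text into maximal runs of letters/digits/apostrophes, lowercased.

    Punctuation (including hyphens) and whitespace are separators, so
    "HER2-positive" yields ["her2", "positive"].
    """
    return _TOKEN_RE.findall(text.lower())


def remove_stopwords(tokens: Iterable[str], stoplist: set[str]) -> list[str]:
    """Order-preserving removal of stop-list members."""
    return [t for t in tokens if t not in stoplist]


class PorterStemmer:
    """The Porter (1980) suffix-stripping algorithm.

    Operates on lowercase alphabetic words; tokens containing digits or
    apostrophes are returned unchanged (the algorithm is defined over
    letters only).  The implementation follows the original five-step rule
    set, including the 'longest matching suffix' convention within each
    rule group.
    """

    _VOWELS = "aeiou"

    def stem(self, word: str) -> str:
        if len(word) <= 2 or not word.isalpha():
            return word
        word = self._step1a(word)
        word = self._step1b(word)
        word = self._step1c(word)
        word = self._step2(word)
        word = self._step3(word)
        word = self._step4(word)
        word = self._step5a(word)
        word = self._step5b(word)
        return word

    # -- letter classification -------------------------------------------

    def _is_cons(self, word: str, i: int) -> bool:
        ch = word[i]
        if ch in self._VOWELS:
            return False
        if ch == "y":
            return i == 0 or not self._is_cons(word, i - 1)
        return True

    def _measure(self, stem: str) -> int:
        """Number of VC sequences in the [C](VC)^m[V] decomposition."""
        m = 0
        prev_vowel = False
        for i in range(len(stem)):
            if self._is_cons(stem, i):
                if prev_vowel:
                    m += 1
                prev_vowel = False
            else:
                prev_vowel = True
        return m

    def _has_vowel(self, stem: str) -> bool:
        return any(not self._is_cons(stem, i) for i in range(len(stem)))

    def _ends_double_cons(self, word: str) -> bool:
        return (
            len(word) >= 2
            and word[-1] == word[-2]
            and self._is_cons(word, len(word) - 1)
        )

    def _ends_cvc(self, word: str) -> bool:
        if len(word) < 3:
            return False
        return (
            self._is_cons(word, len(word) - 3)
            and not self._is_cons(word, len(word) - 2)
            and self._is_cons(word, len(word) - 1)
            and word[-1] not in "wxy"
        )

    # -- steps ------------------------------------------------------------

    def _step1a(self, w: str) -> str:
        if w.endswith("sses"):
            return w[:-2]
        if w.endswith("ies"):
            return w[:-2]
        if w.endswith("ss"):
            return w
        if w.endswith("s"):
            return w[:-1]
        return w

    def _step1b(self, w: str) -> str:
        if w.endswith("eed"):
            if self._measure(w[:-3]) > 0:
                return w[:-1]
            return w
        stripped = None
        if w.endswith("ed") and self._has_vowel(w[:-2]):
            stripped = w[:-2]
        elif w.endswith("ing") and self._has_vowel(w[:-3]):
            stripped = w[:-3]
        if stripped is None:
            return w
        if stripped.endswith(("at", "bl", "iz")):
            return stripped + "e"
        if self._ends_double_cons(stripped) and not stripped.endswith(("l", "s", "z")):
            return stripped[:-1]
        if self._measure(stripped) == 1 and self._ends_cvc(stripped):
            return stripped + "e"
        return stripped

    def _step1c(self, w: str) -> str:
        if w.endswith("y") and self._has_vowel(w[:-1]):
            return w[:-1] + "i"
        return w

    _STEP2 = (
        ("ational", "ate"),
        ("ization", "ize"),
        ("iveness", "ive"),
        ("fulness", "ful"),
        ("ousness", "ous"),
        ("tional", "tion"),
        ("biliti", "ble"),
        ("entli", "ent"),
        ("ousli", "ous"),
        ("ation", "ate"),
        ("alism", "al"),
        ("aliti", "al"),
        ("iviti", "ive"),
        ("enci", "ence"),
        ("anci", "ance"),
        ("izer", "ize"),
        ("abli", "able"),
        ("alli", "al"),
        ("ator", "ate"),
        ("eli", "e"),
    )

    _STEP3 = (
        ("icate", "ic"),
        ("ative", ""),
        ("alize", "al"),
        ("iciti", "ic"),
        ("ical", "ic"),
        ("ful", ""),
        ("ness", ""),
    )

    _STEP4 = (
        "ement",
        "ance",
        "ence",
        "able",
        "ible",
        "ment",
        "ant",
        "ent",
        "ism",
        "ate",
        "iti",
        "ous",
        "ive",
        "ize",
        "ion",
        "al",
        "er",
        "ic",
        "ou",
    )

    def _longest_suffix(self, w: str, suffixes: Iterable[str]) -> Optional[str]:
        best = None
        for s in suffixes:
            if w.endswith(s) and (best is None or len(s) > len(best)):
                best = s
        return best

    def _step2(self, w: str) -> str:
        suf = self._longest_suffix(w, [s for s, _ in self._STEP2])
        if suf is None:
            return w
        repl = dict(self._STEP2)[suf]
        stem = w[: -len(suf)]
        if self._measure(stem) > 0:
            return stem + repl
        return w

    def _step3(self, w: str) -> str:
        suf = self._longest_suffix(w, [s for s, _ in self._STEP3])
        if suf is None:
            return w
        repl = dict(self._STEP3)[suf]
        stem = w[: -len(suf)]
        if self._measure(stem) > 0:
            return stem + repl
        return w

    def _step4(self, w: str) -> str:
        suf = self._longest_suffix(w, self._STEP4)
        if suf is None:
            return w
        stem = w[: -len(suf)]
        if self._measure(stem) <= 1:
            return w
        if suf == "ion" and not stem.endswith(("s", "t")):
            return w
        return stem

    def _step5a(self, w: str) -> str:
        if w.endswith("e"):
            stem = w[:-1]
            m = self._measure(stem)
            if m > 1 or (m == 1 and not self._ends_cvc(stem)):
                return stem
        return w

    def _step5b(self, w: str) -> str:
        if self._measure(w) > 1 and self._ends_double_cons(w) and w.endswith("l"):
            return w[:-1]
        return w


_STEMMER = PorterStemmer()


def stem(tokens: Iterable[str]) -> list[str]:
    """Porter-stem each token; length-preserving."""
    return [_STEMMER.stem(t) for t in tokens]


def preprocess_message(message: Message, stoplist: set[str]) -> TokenSequence:
    """tokenize -> (raw view) -> stop-word removal -> stem -> (stemmed view)."""
    raw = tokenize(message.text)
    stemmed = stem(remove_stopwords(raw, stoplist))
    return TokenSequence(raw_tokens=tuple(raw), stemmed_tokens=tuple(stemmed))


def load_stoplist(path: str | Path) -> set[str]:
    """Plain-text stop list: one lowercase word per line, '#' comments."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            word = line.split("#", 1)[0].strip()
            if word:
                out.add(word.lower())
    return out


def default_stoplist() -> set[str]:
    """The stop-word list shipped with the package."""
    ref = resources.files("healthtopics").joinpath("data/stopwords.txt")
    out: set[str] = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip()
        if word:
            out.add(word.lower())
    return out
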