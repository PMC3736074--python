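"""Labeled message corpora: reading, writing, and summarising.

A corpus is an ordered collection of forum messages, each carrying a unique
id, free text, and an optional topic label.  The label set is ordered by
first appearance; that order defines the class index used everywhere
downstream (class priors, confusion-matrix rows, tie-breaking).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

__all__ = ["Message", "LabeledCorpus", "read_corpus", "write_corpus", "corpus_summary"]


@dataclass(frozen=True)
class Message:
    """One forum message.

    ``label`` is None for unlabeled messages (legal on read; training and
    evaluation operations reject them).  ``text`` may be empty.
    """

    id: str
    text: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("message id must be non-empty")


@dataclass
class LabeledCorpus:
    """Ordered messages plus the ordered set of distinct topic labels.

    ``label_set`` is derived in first-appearance order and is therefore
    stable across re-reads of the same file.
    """

    messages: list[Message] = field(default_factory=list)
    label_set: list[str] = field(default_factory=list)

    @classmethod
    def from_messages(cls, messages: Iterable[Message]) -> "LabeledCorpus":
        msgs = list(messages)
        seen_ids: set[str] = set()
        labels: list[str] = []
        for m in msgs:
            if m.id in seen_ids:
                raise ValueError(f"duplicate message id: {m.id!r}")
            seen_ids.add(m.id)
            if m.label is not None and m.label not in labels:
                labels.append(m.label)
        return cls(messages=msgs, label_set=labels)

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self) -> Iterator[Message]:
        return iter(self.messages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledCorpus):
            return NotImplemented
        return self.messages == other.messages and self.label_set == other.label_set

    @property
    def labels(self) -> list[Optional[str]]:
        return [m.label for m in self.messages]

    def class_indices(self) -> list[int]:
        """Integer class index per message (requires every message labeled)."""
        index = {lab: i for i, lab in enumerate(self.label_set)}
        out = []
        for m in self.messages:
            if m.label is None:
                raise ValueError(f"message {m.id!r} is unlabeled")
            out.append(index[m.label])
        return out

    def subset(self, indices: Sequence[int]) -> "LabeledCorpus":
        """Row subset preserving the full corpus's label order."""
        msgs = [self.messages[i] for i in indices]
        return LabeledCorpus(messages=msgs, label_set=list(self.label_set))


def read_corpus(path: str | Path, format: Optional[str] = None) -> LabeledCorpus:
    """Read a labeled corpus from JSONL or CSV.

    JSONL: one object per line with fields ``id``, ``text`` and optional
    ``label``.  CSV: RFC-4180, header row ``id,text,label`` (label column
    optional; empty cells mean unlabeled).  ``format`` is inferred from the
    file extension when omitted.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "jsonl":
        records = _read_jsonl(path)
    elif fmt == "csv":
        records = _read_csv(path)
    else:
        raise ValueError(f"unknown corpus format: {fmt!r} (expected 'jsonl' or 'csv')")
    return LabeledCorpus.from_messages(records)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer corpus format from {path.name!r}; pass format=")


def _read_jsonl(path: Path) -> list[Message]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path.name}:{lineno}: malformed JSON record: {exc}") from exc
            out.append(_record_to_message(rec, path, lineno))
    return out


def _read_csv(path: Path) -> list[Message]:
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "text" not in reader.fieldnames:
            raise ValueError(f"{path.name}: CSV header must contain 'id' and 'text' columns")
        for lineno, rec in enumerate(reader, start=2):
            if rec.get("label") == "":
                rec = dict(rec, label=None)
            out.append(_record_to_message(rec, path, lineno))
    return out


def _record_to_message(rec: dict, path: Path, lineno: int) -> Message:
    if not isinstance(rec, dict) or "id" not in rec or rec["id"] in (None, "") or "text" not in rec or rec["text"] is None:
        raise ValueError(f"{path.name}:{lineno}: record must have non-empty 'id' and a 'text' field")
    label = rec.get("label")
    return Message(id=str(rec["id"]), text=str(rec["text"]), label=None if label is None else str(label))


def write_corpus(corpus: LabeledCorpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus so that :func:`read_corpus` reproduces it exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for m in corpus:
                rec = {"id": m.id, "text": m.text}
                if m.label is not None:
                    rec["label"] = m.label
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text", "label"])
            for m in corpus:
                writer.writerow([m.id, m.text, "" if m.label is None else m.label])
    else:
        raise ValueError(f"unknown corpus format: {fmt!r} (expected 'jsonl' or 'csv')")


def corpus_summary(corpus: LabeledCorpus) -> dict:
    """Per-label message counts plus totals.

    Returns ``{"total": N, "labeled": L, "counts": {label: n, ...}}`` with
    counts keyed in label-set order; counts sum to ``labeled``.
    """
    counter = Counter(m.label for m in corpus if m.label is not None)
    counts = {lab: counter.get(lab, 0) for lab in corpus.label_set}
    return {"total": len(corpus), "labeled": sum(counts.values()), "counts": counts}
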