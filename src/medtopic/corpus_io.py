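"""Reading, writing, validating and summarizing message corpora.

A corpus is an ordered collection of forum posts ("messages") from one
disease discussion board. The canonical on-disk format is JSONL (one
UTF-8 JSON record per line); CSV with RFC-4180 quoting is supported for
interoperability. Record keys / CSV columns, in order:

    id, author_id, board_id, timestamp, text, gold_label, thread_id

``id``, ``author_id`` and ``text`` are required; the rest are optional.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "Message",
    "Corpus",
    "CorpusStats",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "corpus_stats",
    "messages_per_member",
]

_FIELDS = ("id", "author_id", "board_id", "timestamp", "text", "gold_label", "thread_id")
_REQUIRED = ("id", "author_id", "text")


class CorpusFormatError(ValueError):
    """A malformed corpus file (bad record, missing field, duplicate id)."""


@dataclass(frozen=True)
class Message:
    """One forum post."""

    id: str
    author_id: str
    text: str
    board_id: str = ""
    timestamp: Optional[str] = None
    gold_label: Optional[str] = None
    thread_id: Optional[str] = None


@dataclass
class Corpus:
    """Ordered messages from one discussion board."""

    messages: list[Message] = field(default_factory=list)
    board_name: str = ""
    disease_type: str = ""

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.messages:
            if not m.id:
                raise CorpusFormatError("message with empty id")
            if m.id in seen:
                raise CorpusFormatError(f"duplicate message id {m.id!r}")
            seen.add(m.id)


@dataclass(frozen=True)
class CorpusStats:
    n_messages: int
    n_members: int
    messages_per_member: float
    time_span: Optional[tuple[datetime, datetime]]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def _record_to_message(rec: dict, line_no: int) -> Message:
    for key in _REQUIRED:
        if key not in rec or rec[key] is None or (key != "text" and rec[key] == ""):
            raise CorpusFormatError(f"line {line_no}: missing required field {key!r}")
    kwargs = {}
    for key in _FIELDS:
        v = rec.get(key)
        if key in ("board_id",):
            kwargs[key] = v or ""
        elif key in ("timestamp", "gold_label", "thread_id"):
            kwargs[key] = v if v not in (None, "") else None
        else:
            kwargs[key] = str(v)
    return Message(**kwargs)


def read_corpus(path, format: Optional[str] = None, board_name: str = "",
                disease_type: str = "") -> Corpus:
    """Read a corpus file, preserving record order.

    Raises :class:`CorpusFormatError` naming the line for malformed records,
    missing required fields and duplicate ids.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    messages: list[Message] = []
    seen: dict[str, int] = {}

    def add(rec: dict, line_no: int) -> None:
        msg = _record_to_message(rec, line_no)
        if msg.id in seen:
            raise CorpusFormatError(
                f"line {line_no}: duplicate id {msg.id!r} (first seen line {seen[msg.id]})"
            )
        seen[msg.id] = line_no
        messages.append(msg)

    with path.open("r", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"line {line_no}: invalid JSON ({exc.msg})") from exc
                if not isinstance(rec, dict):
                    raise CorpusFormatError(f"line {line_no}: record is not an object")
                add(rec, line_no)
        else:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                pass  # empty file -> empty corpus
            else:
                missing = [c for c in _REQUIRED if c not in reader.fieldnames]
                if missing:
                    raise CorpusFormatError(f"line 1: header missing column(s) {missing}")
                for rec in reader:
                    add(rec, reader.line_num)
    return Corpus(messages=messages, board_name=board_name, disease_type=disease_type)


def write_corpus(corpus: Corpus, path, format: Optional[str] = None) -> None:
    """Write a corpus; ``read_corpus`` on the result reproduces every field."""
    path = Path(path)
    fmt = _infer_format(path, format)
    corpus.validate()
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt == "jsonl":
            for m in corpus.messages:
                rec = {k: getattr(m, k) for k in _FIELDS}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
        else:
            writer = csv.writer(fh)
            writer.writerow(_FIELDS)
            for m in corpus.messages:
                writer.writerow(
                    ["" if getattr(m, k) is None else getattr(m, k) for k in _FIELDS]
                )


def messages_per_member(n_messages: int, n_members: int) -> float:
    """Messages-per-member ratio, rounded half-up to 2 decimals."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    ratio = Decimal(n_messages) / Decimal(n_members)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _parse_timestamp(raw: str) -> Optional[datetime]:
    try:
        return datetime.fromisoformat(raw)
    except (ValueError, TypeError):
        return None


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Summary statistics: message/member counts, ratio, time span.

    Timestamps are parsed leniently as ISO-8601; unparseable ones are
    ignored for the time span. An empty corpus is an error (the ratio is
    undefined).
    """
    if len(corpus) == 0:
        raise ValueError("corpus_stats undefined for an empty corpus")
    n_messages = len(corpus)
    members = {m.author_id for m in corpus}
    parsed = [t for t in (_parse_timestamp(m.timestamp) for m in corpus if m.timestamp)
              if t is not None]
    span = (min(parsed), max(parsed)) if parsed else None
    return CorpusStats(
        n_messages=n_messages,
        n_members=len(members),
        messages_per_member=messages_per_member(n_messages, len(members)),
        time_span=span,
    )
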