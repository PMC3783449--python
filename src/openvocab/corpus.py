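"""Message-corpus and outcome-table I/O, author aggregation and inclusion filters.

The document unit is a single short message (a status update); the unit of
analysis is the author.  Messages are pooled per author for counting, but
message boundaries are retained so that downstream n-gram extraction never
builds a phrase spanning two messages.

Authors enter the analysis only if they pass the inclusion criteria used for
the study design this package supports: a minimum amount of written text
(default 1,000 word tokens), an age ceiling (default: strictly younger than
65 years), and presence of the outcomes used as statistical controls.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Message",
    "AuthorRecord",
    "FilterCriteria",
    "AuthorCorpus",
    "read_messages",
    "read_outcomes",
    "aggregate_authors",
    "filter_authors",
]


@dataclass(frozen=True)
class Message:
    """One message: who wrote it and its raw text (may be empty)."""

    author_id: str
    text: str
    message_id: Optional[str] = None

    def __post_init__(self):
        if not self.author_id:
            raise ValueError("author_id must be non-empty")


@dataclass
class AuthorRecord:
    """Per-author aggregate: outcome values and token counts."""

    author_id: str
    outcomes: Dict[str, float] = field(default_factory=dict)
    n_messages: int = 0
    n_words: int = 0


@dataclass(frozen=True)
class FilterCriteria:
    """Author-inclusion thresholds.

    ``max_age`` is exclusive (an author aged exactly ``max_age`` is dropped);
    ``min_words`` is inclusive.  ``required_outcomes`` must all be present
    (non-missing) for an author to be kept.
    """

    min_words: int = 1000
    max_age: float = 65.0
    required_outcomes: Sequence[str] = ()
    age_name: str = "age"

    def __post_init__(self):
        if self.min_words < 0:
            raise ValueError("min_words must be >= 0")


def read_messages(path, format: str = "csv") -> Iterator[Message]:
    """Yield :class:`Message` records from a CSV or JSON-lines file, in order.

    CSV files must have a header with ``author_id`` and ``text`` columns
    (``message_id`` optional, RFC-4180 quoting).  JSON-lines files hold one
    object per line with the same keys.  Malformed rows raise ``ValueError``
    naming the offending row number.
    """
    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"author_id", "text"} <= set(
                reader.fieldnames
            ):
                raise ValueError(
                    "message CSV must have author_id and text columns"
                )
            for i, row in enumerate(reader, start=2):
                if row.get("author_id") is None or row.get("text") is None:
                    raise ValueError(f"malformed message row {i} in {path}")
                yield Message(row["author_id"], row["text"], row.get("message_id"))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    yield Message(obj["author_id"], obj["text"], obj.get("message_id"))
                except (json.JSONDecodeError, KeyError, TypeError) as exc:
                    raise ValueError(
                        f"malformed message row {i} in {path}: {exc}"
                    ) from exc
    else:
        raise ValueError(f"unknown message format: {format!r}")


def write_messages(path, messages: Iterable[Message], format: str = "csv") -> None:
    """Inverse of :func:`read_messages` (used by the synthetic generator)."""
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["author_id", "text", "message_id"])
            for m in messages:
                writer.writerow([m.author_id, m.text, m.message_id or ""])
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for m in messages:
                rec = {"author_id": m.author_id, "text": m.text}
                if m.message_id is not None:
                    rec["message_id"] = m.message_id
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown message format: {format!r}")


def read_outcomes(path, covariates: Sequence[str] = ()) -> pd.DataFrame:
    """Read the per-author outcomes table.

    The CSV header names the outcomes; the first column must be ``author_id``.
    Blank cells become missing (NaN); any other non-numeric cell is an error,
    as is a duplicated author_id.  ``covariates`` must be a subset of the
    outcome columns; the designation is stored in ``df.attrs['covariates']``.

    By convention gender is coded 0 (male) to 1 (female).
    """
    df = pd.read_csv(path, dtype={"author_id": str})
    if "author_id" not in df.columns:
        raise ValueError("outcomes table must have an author_id column")
    if df["author_id"].duplicated().any():
        dups = df.loc[df["author_id"].duplicated(), "author_id"].tolist()
        raise ValueError(f"duplicate author_id in outcomes table: {dups[:5]}")
    outcome_cols = [c for c in df.columns if c != "author_id"]
    missing = set(covariates) - set(outcome_cols)
    if missing:
        raise ValueError(f"covariate(s) not in outcomes header: {sorted(missing)}")
    for col in outcome_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in outcome column {col!r}") from exc
    df = df.set_index("author_id")
    df.attrs["covariates"] = list(covariates)
    return df


class AuthorCorpus:
    """Tokenized messages pooled per author.

    Holds, for each author, the list of per-message token lists (so n-grams
    can respect message boundaries) together with unigram counts and totals.
    This is the in-memory container every feature extractor consumes.
    """

    def __init__(self):
        self.messages: Dict[str, List[List[str]]] = {}
        self.unigram_counts: Dict[str, Counter] = {}
        self.records: Dict[str, AuthorRecord] = {}
        self._seen_ids: set = set()

    @property
    def author_ids(self) -> List[str]:
        return list(self.records)

    def add(self, message: Message, tokens: List[str]) -> None:
        if message.message_id is not None:
            key = (message.author_id, message.message_id)
            if key in self._seen_ids:
                warnings.warn(
                    f"dropping duplicate message {key}", stacklevel=2
                )
                return
            self._seen_ids.add(key)
        rec = self.records.get(message.author_id)
        if rec is None:
            rec = AuthorRecord(message.author_id)
            self.records[message.author_id] = rec
            self.messages[message.author_id] = []
            self.unigram_counts[message.author_id] = Counter()
        rec.n_messages += 1
        rec.n_words += len(tokens)
        self.messages[message.author_id].append(tokens)
        self.unigram_counts[message.author_id].update(tokens)

    def attach_outcomes(self, outcomes: pd.DataFrame) -> None:
        for aid, rec in self.records.items():
            if aid in outcomes.index:
                row = outcomes.loc[aid]
                rec.outcomes = {
                    k: float(v) for k, v in row.items() if pd.notna(v)
                }

    def subset(self, author_ids: Sequence[str]) -> "AuthorCorpus":
        sub = AuthorCorpus()
        for aid in author_ids:
            sub.messages[aid] = self.messages[aid]
            sub.unigram_counts[aid] = self.unigram_counts[aid]
            sub.records[aid] = self.records[aid]
        return sub


def aggregate_authors(
    messages: Iterable[Message],
    tokenizer: Callable[[str], List[str]],
) -> AuthorCorpus:
    """Tokenize a message stream and pool counts per author.

    ``n_words`` counts unigram tokens over all of an author's messages; an
    empty message still increments ``n_messages``.
    """
    corpus = AuthorCorpus()
    for message in messages:
        corpus.add(message, tokenizer(message.text))
    return corpus


def filter_authors(
    records: Dict[str, AuthorRecord], criteria: FilterCriteria
) -> Dict[str, AuthorRecord]:
    """Apply the author-inclusion criteria; output is a subset of the input.

    An author is kept iff ``n_words >= min_words``, every required outcome is
    present, and (when the age outcome is available) ``age < max_age``.  A
    missing age only excludes an author if age is itself required.
    """
    kept: Dict[str, AuthorRecord] = {}
    for aid, rec in records.items():
        if rec.n_words < criteria.min_words:
            continue
        if any(name not in rec.outcomes for name in criteria.required_outcomes):
            continue
        age = rec.outcomes.get(criteria.age_name)
        if age is not None and age >= criteria.max_age:
            continue
        kept[aid] = rec
    return kept
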