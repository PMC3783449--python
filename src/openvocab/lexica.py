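"""Closed-vocabulary (word-category) features.

A lexicon maps category names to lists of word patterns — literal tokens or
stem wildcards with a trailing ``*`` (``happ*`` matches any token starting
with "happ").  A category's feature value for an author is the fraction of
that author's word tokens matching any pattern of the category, i.e. the
percentage of the author's words that come from the category.

Matching operates on unigrams only; categories may overlap (a token can
count toward several categories), but within one category a token counts
once no matter how many patterns it matches.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .corpus import AuthorCorpus
from .features import FeatureMatrix

__all__ = ["Lexicon", "load_lexicon", "category_relative_frequency",
           "lexicon_feature_matrix"]


@dataclass
class Lexicon:
    """category name -> list of patterns (literal token or trailing-* stem)."""

    categories: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self):
        for name, patterns in self.categories.items():
            for p in patterns:
                if " " in p.strip():
                    warnings.warn(
                        f"multiword pattern {p!r} in category {name!r} ignored "
                        "(matching is unigram-only)", stacklevel=2
                    )
        self.categories = {
            name: [p for p in patterns if " " not in p.strip()]
            for name, patterns in self.categories.items()
        }

    def names(self) -> List[str]:
        return list(self.categories)


def load_lexicon(path, dialect: str = "csv") -> Lexicon:
    """Load a lexicon file.

    ``csv``: rows of (category, term).  ``dic``: the LIWC-style format — a
    header block delimited by ``%`` lines mapping numeric category ids to
    names, then ``term<TAB>id [id ...]`` body lines.  An id in the body that
    was never declared in the header is an error.
    """
    categories: Dict[str, List[str]] = {}
    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                cat, term = row[0].strip(), row[1].strip()
                categories.setdefault(cat, []).append(term)
    elif dialect == "dic":
        id_to_name: Dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            in_header = False
            header_done = False
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line == "%":
                    if not in_header and not header_done:
                        in_header = True
                    else:
                        in_header = False
                        header_done = True
                    continue
                if in_header:
                    cid, name = line.split(None, 1)
                    id_to_name[cid] = name.strip()
                    categories.setdefault(name.strip(), [])
                else:
                    parts = line.split()
                    term, ids = parts[0], parts[1:]
                    for cid in ids:
                        if cid not in id_to_name:
                            raise ValueError(
                                f"unknown category id {cid!r} for term {term!r}"
                            )
                        categories[id_to_name[cid]].append(term)
    else:
        raise ValueError(f"unknown lexicon dialect: {dialect!r}")
    return Lexicon(categories)


def _matches(token: str, patterns: Sequence[str]) -> bool:
    for p in patterns:
        if p.endswith("*"):
            if token.startswith(p[:-1]):
                return True
        elif token == p:
            return True
    return False


def category_relative_frequency(
    unigram_counts: Counter, n_words: int, patterns: Sequence[str]
) -> float:
    """Fraction of an author's word tokens matching a category's patterns.

    A token matching several patterns of the category counts once.  Value is
    in [0, 1] and invariant to how the author's text is split into messages.
    """
    if n_words <= 0:
        raise ValueError("author has zero words; filter upstream")
    matched = sum(c for tok, c in unigram_counts.items() if _matches(tok, patterns))
    return matched / n_words


def lexicon_feature_matrix(
    corpus: AuthorCorpus, lexicon: Lexicon, prefix: str = ""
) -> FeatureMatrix:
    """Authors x categories matrix of category relative frequencies."""
    names = lexicon.names()
    authors = corpus.author_ids
    values = np.zeros((len(authors), len(names)))
    for i, aid in enumerate(authors):
        counts = corpus.unigram_counts[aid]
        n_words = corpus.records[aid].n_words
        for j, name in enumerate(names):
            values[i, j] = category_relative_frequency(
                counts, n_words, lexicon.categories[name]
            )
    n_used = (values > 0).sum(axis=0)
    return FeatureMatrix(
        authors, [prefix + n for n in names], values, "category_relfreq",
        n_authors_used=n_used,
    )
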