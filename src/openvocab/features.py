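"""Open-vocabulary word/phrase features.

The feature set is built from the corpus itself: all contiguous 1- to 3-grams
within a message.  Multiword phrases are kept only when pointwise mutual
information (PMI) marks them as genuine collocations rather than accidental
juxtapositions; counts are normalized by each author's total word use, passed
through the Anscombe variance-stabilizing transform
``x -> 2 * sqrt(x + 3/8)``, and features used by fewer than 1% of authors are
discarded to keep the focus on common language.

:class:`NgramVectorizer` composes these steps with a fit/transform split so
corpus statistics (PMI probabilities, usage thresholds) can be learned on
training authors only and applied frozen to held-out authors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import AuthorCorpus

__all__ = [
    "FeatureMatrix",
    "extract_ngrams",
    "pmi",
    "collocation_filter",
    "relative_frequency",
    "anscombe",
    "min_usage_filter",
    "build_feature_matrix",
    "NgramVectorizer",
]

ANSCOMBE_MIN = 2.0 * math.sqrt(3.0 / 8.0)   # value at p = 0
ANSCOMBE_MAX = 2.0 * math.sqrt(11.0 / 8.0)  # value at p = 1


@dataclass
class FeatureMatrix:
    """Authors x features value grid.

    ``kind`` tags the value semantics: ``anscombe_relfreq`` (n-grams),
    ``relfreq``, ``category_relfreq`` (lexicon categories) or ``topic_prob``
    (p(topic | author)).  ``n_authors_used`` records, per feature, how many
    authors used it at least once (the provenance needed by the usage
    filter); ``corpus_frequency`` is the feature's total corpus count.
    """

    authors: List[str]
    features: List[str]
    values: np.ndarray
    kind: str
    corpus_frequency: Optional[np.ndarray] = None
    n_authors_used: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.authors), len(self.features)):
            raise ValueError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.authors)} authors x {len(self.features)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.authors, columns=self.features)

    def subset_authors(self, author_ids: Sequence[str]) -> "FeatureMatrix":
        idx = {a: i for i, a in enumerate(self.authors)}
        rows = [idx[a] for a in author_ids]
        return FeatureMatrix(
            list(author_ids),
            list(self.features),
            self.values[rows],
            self.kind,
            self.corpus_frequency,
            self.n_authors_used,
        )

    def hstack(self, other: "FeatureMatrix", dedup: bool = True) -> "FeatureMatrix":
        """Column-concatenate two matrices over the same authors.

        With ``dedup`` (default) a column of ``other`` whose feature name is
        already present is dropped, so a union of a set with itself equals
        the set alone.
        """
        if self.authors != other.authors:
            raise ValueError("hstack requires identical author ordering")
        if dedup:
            seen = set(self.features)
            keep = [j for j, f in enumerate(other.features) if f not in seen]
        else:
            keep = list(range(len(other.features)))
        values = np.hstack([self.values, other.values[:, keep]])
        feats = self.features + [other.features[j] for j in keep]
        kind = self.kind if self.kind == other.kind else "mixed"
        return FeatureMatrix(self.authors, feats, values, kind)

    def to_wide_csv(self, path) -> None:
        self.to_frame().rename_axis("author_id").to_csv(path)

    def to_triplet_csv(self, path) -> None:
        rows = np.nonzero(self.values)
        df = pd.DataFrame(
            {
                "author_id": [self.authors[i] for i in rows[0]],
                "feature": [self.features[j] for j in rows[1]],
                "value": self.values[rows],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path, kind: str) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="author_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy(), kind)


def extract_ngrams(tokens: Sequence[str], n_max: int = 3) -> Counter:
    """All contiguous n-grams (1..n_max) of one message, as a multiset.

    N-grams are tuples of tokens; callers must never concatenate token lists
    across messages (phrases do not span message boundaries).
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    grams: Counter = Counter()
    L = len(tokens)
    for n in range(1, n_max + 1):
        for i in range(L - n + 1):
            grams[tuple(tokens[i : i + n])] += 1
    return grams


def pmi(
    phrase_prob: float, word_probs: Sequence[float], base: Optional[float] = None
) -> float:
    """Pointwise mutual information of a phrase, in log units.

    ``log[p(phrase) / prod_i p(word_i)]`` — natural log by default (pass
    ``base`` for another).  A phrase probability of zero returns ``-inf``
    (such a phrase can never pass the collocation filter).
    """
    if any(p <= 0 for p in word_probs):
        raise ValueError("all component word probabilities must be positive")
    if phrase_prob < 0:
        raise ValueError("phrase probability must be >= 0")
    if phrase_prob == 0:
        return float("-inf")
    value = math.log(phrase_prob) - sum(math.log(p) for p in word_probs)
    if base is not None:
        value /= math.log(base)
    return value


def default_pmi_threshold(n: int, coef: float = 2.0) -> float:
    """Phrase-length–scaled PMI threshold (natural-log units): ``coef * n``."""
    return coef * n


def collocation_filter(
    corpus_counts: Dict[Tuple[str, ...], int],
    totals: Dict[int, int],
    threshold_fn: Callable[[int], float] = default_pmi_threshold,
) -> set:
    """Retain unigrams unconditionally, phrases only when PMI clears the bar.

    ``corpus_counts`` maps n-gram tuples to corpus counts; ``totals[n]`` is
    the total corpus count of n-grams of length n (so that probabilities are
    per-order: p(g) = count(g) / totals[len(g)]).
    """
    word_prob = {
        g[0]: c / totals[1] for g, c in corpus_counts.items() if len(g) == 1
    }
    retained = set()
    for gram, count in corpus_counts.items():
        n = len(gram)
        if n == 1:
            retained.add(gram)
            continue
        if any(w not in word_prob for w in gram):
            continue
        score = pmi(count / totals[n], [word_prob[w] for w in gram])
        if score > threshold_fn(n):
            retained.add(gram)
    return retained


def relative_frequency(
    author_counts: Counter, n_words: int
) -> Dict[Tuple[str, ...], float]:
    """Counts normalized by the author's total word use.

    Phrases are divided by the same unigram total as words (the denominator
    is the author's total word use, not the per-order n-gram count).
    """
    if n_words <= 0:
        raise ValueError("author has zero words; filter upstream")
    return {g: c / n_words for g, c in author_counts.items()}


def anscombe(p):
    """Variance-stabilizing transform ``2 * sqrt(p + 3/8)`` for p in [0, 1].

    Accepts scalars or arrays; values outside [0, 1] raise ``ValueError``.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("relative frequencies must lie in [0, 1]")
    out = 2.0 * np.sqrt(arr + 0.375)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def min_usage_filter(
    matrix: FeatureMatrix, min_author_fraction: float = 0.01
) -> FeatureMatrix:
    """Drop features used by fewer than ``ceil(frac * n_authors)`` authors."""
    if matrix.n_authors_used is None:
        raise ValueError("matrix lacks usage provenance (n_authors_used)")
    need = math.ceil(min_author_fraction * len(matrix.authors))
    keep = np.nonzero(matrix.n_authors_used >= need)[0]
    return FeatureMatrix(
        matrix.authors,
        [matrix.features[j] for j in keep],
        matrix.values[:, keep],
        matrix.kind,
        None if matrix.corpus_frequency is None else matrix.corpus_frequency[keep],
        matrix.n_authors_used[keep],
    )


def feature_name(gram: Tuple[str, ...]) -> str:
    """Display name: words of a phrase joined with underscores."""
    return "_".join(gram)


def build_feature_matrix(
    corpus: AuthorCorpus,
    retained: Iterable[Tuple[str, ...]],
    n_max: int = 3,
) -> FeatureMatrix:
    """Assemble the Anscombe-transformed relative-frequency matrix.

    Reference (dictionary-based) assembly: one row per author, one column per
    retained n-gram; an author who never uses a feature gets ``anscombe(0)``.
    For large corpora prefer :class:`NgramVectorizer`, which is vectorized
    but computes the same values.
    """
    feats = sorted(retained, key=lambda g: (len(g), g))
    col = {g: j for j, g in enumerate(feats)}
    authors = corpus.author_ids
    raw = np.zeros((len(authors), len(feats)))
    for i, aid in enumerate(authors):
        counts: Counter = Counter()
        for msg in corpus.messages[aid]:
            for g, c in extract_ngrams(msg, n_max).items():
                if g in col:
                    counts[g] += c
        rel = relative_frequency(counts, corpus.records[aid].n_words)
        for g, v in rel.items():
            raw[i, col[g]] = v
    n_used = (raw > 0).sum(axis=0)
    return FeatureMatrix(
        authors,
        [feature_name(g) for g in feats],
        anscombe(raw),
        "anscombe_relfreq",
        n_authors_used=n_used,
    )


class NgramVectorizer:
    """Fit/transform n-gram feature extraction with frozen corpus statistics.

    ``fit`` learns the vocabulary, per-order corpus probabilities, the
    PMI-retained phrase set and the usage filter from one corpus (e.g. the
    training authors); ``transform`` evaluates the frozen feature set on any
    corpus.  Implementation is integer-encoded and vectorized, but value
    semantics match the reference ops above exactly.
    """

    def __init__(
        self,
        n_max: int = 3,
        pmi_threshold_coef: float = 2.0,
        min_author_fraction: float = 0.01,
        prefix: str = "",
    ):
        if n_max < 1 or n_max > 3:
            raise ValueError("n_max must be 1..3")
        self.n_max = n_max
        self.pmi_threshold_coef = pmi_threshold_coef
        self.min_author_fraction = min_author_fraction
        self.prefix = prefix

    # -- encoding helpers -------------------------------------------------
    def _encode(self, corpus: AuthorCorpus, vocab: Dict[str, int]):
        """Flatten a corpus to parallel arrays (word id, author idx, msg id).

        Out-of-vocabulary tokens get id -1 (they still count toward author
        word totals but can never form a known feature).
        """
        get = vocab.get
        words = np.fromiter(
            (
                get(tok, -1)
                for aid in corpus.author_ids
                for msg in corpus.messages[aid]
                for tok in msg
            ),
            dtype=np.int64,
        )
        msg_lens = np.fromiter(
            (
                len(msg)
                for aid in corpus.author_ids
                for msg in corpus.messages[aid]
            ),
            dtype=np.int64,
        )
        msg_author = np.fromiter(
            (
                i
                for i, aid in enumerate(corpus.author_ids)
                for _ in corpus.messages[aid]
            ),
            dtype=np.int64,
        )
        authors_ix = np.repeat(msg_author, msg_lens)
        msg_ids = np.repeat(np.arange(len(msg_lens)), msg_lens)
        return words, authors_ix, msg_ids

    def _gram_keys(self, words, msg_ids, n):
        """Integer keys of all within-message n-grams, base |V|."""
        V = len(self.vocab_)
        if n == 1:
            valid = words >= 0
            return words[valid], valid.nonzero()[0]
        key = words[: len(words) - n + 1].copy()
        valid = (words[: len(words) - n + 1] >= 0) & (
            msg_ids[: len(msg_ids) - n + 1] == msg_ids[n - 1 :]
        )
        for j in range(1, n):
            nxt = words[j : len(words) - n + 1 + j]
            valid &= nxt >= 0
            key = key * V + nxt
        return key[valid], valid.nonzero()[0]

    @staticmethod
    def _decode_key(key: int, V: int, n: int, ivocab: List[str]) -> Tuple[str, ...]:
        out = []
        for _ in range(n):
            out.append(ivocab[key % V])
            key //= V
        return tuple(reversed(out))

    # -- fitting ----------------------------------------------------------
    def fit(self, corpus: AuthorCorpus) -> "NgramVectorizer":
        vocab_counter: Counter = Counter()
        for counts in corpus.unigram_counts.values():
            vocab_counter.update(counts)
        self.vocab_ = {w: i for i, w in enumerate(sorted(vocab_counter))}
        ivocab = sorted(vocab_counter)
        V = len(self.vocab_)
        words, authors_ix, msg_ids = self._encode(corpus, self.vocab_)

        # per-order corpus counts and totals
        self._corpus_keys: Dict[int, np.ndarray] = {}
        self._corpus_counts: Dict[int, np.ndarray] = {}
        self.totals_: Dict[int, int] = {}
        for n in range(1, self.n_max + 1):
            keys, _ = self._gram_keys(words, msg_ids, n)
            # totals include every in-message n-gram position (OOV impossible
            # at fit time: the vocabulary comes from this corpus)
            uk, uc = np.unique(keys, return_counts=True)
            self._corpus_keys[n] = uk
            self._corpus_counts[n] = uc
            self.totals_[n] = int(uc.sum())

        # PMI collocation filter over phrases
        log_word_prob = np.full(V, -np.inf)
        uk1, uc1 = self._corpus_keys[1], self._corpus_counts[1]
        log_word_prob[uk1] = np.log(uc1 / self.totals_[1])
        retained: List[Tuple[int, int]] = [(1, k) for k in uk1]  # (order, key)
        for n in range(2, self.n_max + 1):
            if self.totals_[n] == 0:
                continue
            uk, uc = self._corpus_keys[n], self._corpus_counts[n]
            log_joint = np.log(uc / self.totals_[n])
            indep = np.zeros(len(uk))
            key = uk.copy()
            for _ in range(n):
                indep += log_word_prob[key % V]
                key //= V
            scores = log_joint - indep
            thr = default_pmi_threshold(n, self.pmi_threshold_coef)
            for k in uk[scores > thr]:
                retained.append((n, int(k)))

        # per-author counts of retained features; usage filter
        authors = corpus.author_ids
        n_authors = len(authors)
        word_totals = np.array(
            [corpus.records[a].n_words for a in authors], dtype=float
        )
        if np.any(word_totals <= 0):
            bad = [a for a, t in zip(authors, word_totals) if t <= 0]
            raise ValueError(f"authors with zero words must be filtered out: {bad[:5]}")

        need = math.ceil(self.min_author_fraction * n_authors)
        raw, n_used, corpus_freq, feats = self._count_retained(
            words, authors_ix, msg_ids, retained, n_authors, word_totals,
            min_authors=need,
        )
        keep = np.nonzero(n_used >= need)[0]
        self.features_ = [feats[j] for j in keep]
        self.feature_names_ = [
            self.prefix + feature_name(g) for g in self.features_
        ]
        self.corpus_frequency_ = corpus_freq[keep]
        self._fit_cache = FeatureMatrix(
            authors,
            self.feature_names_,
            anscombe(raw[:, keep] / word_totals[:, None]),
            "anscombe_relfreq",
            self.corpus_frequency_,
            n_used[keep],
        )
        return self

    def _count_retained(self, words, authors_ix, msg_ids, retained, n_authors,
                        word_totals, min_authors: int = 0):
        """Per-author counts of retained n-grams, author usage and totals.

        ``min_authors`` lets the caller drop candidates used by too few
        authors *before* the dense grid is materialized (rare PMI-passing
        phrases can vastly outnumber the survivors).
        """
        V = len(self.vocab_)
        ivocab = sorted(self.vocab_)
        cols: List[Tuple[str, ...]] = []
        raw_cols = []
        used_cols = []
        freq_cols = []
        by_order: Dict[int, List[int]] = {}
        for n, k in retained:
            by_order.setdefault(n, []).append(k)
        for n in sorted(by_order):
            want = np.asarray(sorted(by_order[n]), dtype=np.int64)
            keys, pos = self._gram_keys(words, msg_ids, n)
            ix = np.searchsorted(want, keys)
            ix_ok = ix < len(want)
            ix_clip = np.where(ix_ok, ix, 0)
            hit = ix_ok & (want[ix_clip] == keys)
            f_ix = ix_clip[hit]
            a_ix = authors_ix[pos[hit]]
            pair = f_ix * n_authors + a_ix
            up, uc = np.unique(pair, return_counts=True)
            uf, ua = up // n_authors, up % n_authors
            if min_authors > 0:
                per_feat_users = np.bincount(uf, minlength=len(want))
                ok_feat = per_feat_users >= min_authors
                remap = np.cumsum(ok_feat) - 1
                sel = ok_feat[uf]
                uf, ua, uc = remap[uf[sel]], ua[sel], uc[sel]
                want = want[ok_feat]
            grid = np.zeros((n_authors, len(want)))
            grid[ua, uf] = uc
            raw_cols.append(grid)
            used_cols.append((grid > 0).sum(axis=0))
            freq_cols.append(grid.sum(axis=0))
            cols.extend(self._decode_key(int(k), V, n, ivocab) for k in want)
        raw = np.hstack(raw_cols) if raw_cols else np.zeros((n_authors, 0))
        n_used = np.concatenate(used_cols) if used_cols else np.zeros(0)
        freq = np.concatenate(freq_cols) if freq_cols else np.zeros(0)
        return raw, n_used, freq, cols

    def fit_transform(self, corpus: AuthorCorpus) -> FeatureMatrix:
        self.fit(corpus)
        return self._fit_cache

    def transform(self, corpus: AuthorCorpus) -> FeatureMatrix:
        if not hasattr(self, "features_"):
            raise RuntimeError("vectorizer is not fitted")
        if (
            hasattr(self, "_fit_cache")
            and corpus.author_ids == self._fit_cache.authors
        ):
            return self._fit_cache
        words, authors_ix, msg_ids = self._encode(corpus, self.vocab_)
        authors = corpus.author_ids
        word_totals = np.array(
            [corpus.records[a].n_words for a in authors], dtype=float
        )
        if np.any(word_totals <= 0):
            raise ValueError("authors with zero words must be filtered out")
        V = len(self.vocab_)
        retained = []
        for g in self.features_:
            key = 0
            for w in g:
                key = key * V + self.vocab_[w]
            retained.append((len(g), key))
        raw, n_used, _, feats = self._count_retained(
            words, authors_ix, msg_ids, retained, len(authors), word_totals
        )
        order = {g: j for j, g in enumerate(feats)}
        perm = [order[g] for g in self.features_]
        return FeatureMatrix(
            authors,
            self.feature_names_,
            anscombe(raw[:, perm] / word_totals[:, None]),
            "anscombe_relfreq",
            self.corpus_frequency_,
            n_used[perm],
        )

    def corpus_count_table(self) -> Dict[Tuple[str, ...], int]:
        """Corpus-level n-gram counts (decoded), for the reference ops."""
        V = len(self.vocab_)
        ivocab = sorted(self.vocab_)
        out: Dict[Tuple[str, ...], int] = {}
        for n, (uk, uc) in enumerate(
            zip(self._corpus_keys.values(), self._corpus_counts.values()), start=1
        ):
            for k, c in zip(uk, uc):
                out[self._decode_key(int(k), V, n, ivocab)] = int(c)
        return out

    def word_frequencies(self) -> Dict[str, int]:
        """Corpus unigram counts by surface form (used by phrase pruning)."""
        uk, uc = self._corpus_keys[1], self._corpus_counts[1]
        ivocab = sorted(self.vocab_)
        return {ivocab[int(k)]: int(c) for k, c in zip(uk, uc)}
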