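"""LDA topic estimation by collapsed Gibbs sampling, and topic-usage features.

Messages are the documents: each short message is assumed to mix few topics,
so the document-topic concentration ``alpha`` defaults to a small value.  The
sampler is the standard collapsed Gibbs update over token-topic assignments,

    p(z_i = k | rest)  ~  (c_kw + beta) / (c_k + V*beta) * (c_dk + alpha),

with the topic-word distributions read off the final sample with beta
smoothing: ``p(w|k) = (c_kw + beta) / (c_k + V*beta)``.

An author's topic usage is not inferred per document; following the
feature-extraction recipe this package implements, it is

    p(topic | author) = sum_w p(topic | w) * p(w | author),

where ``p(topic|w)`` comes from the sampler's assignment counts and
``p(w|author)`` is the author's word distribution renormalized over the model
vocabulary.  The inner sampling loop is JIT-compiled with numba.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import AuthorCorpus
from .features import FeatureMatrix

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not a or not callable(a[0]) else a[0]

__all__ = [
    "TopicModel",
    "fit_lda",
    "topic_given_word",
    "topic_usage",
    "topic_usage_matrix",
    "top_words",
    "load_topic_word_table",
]


@dataclass
class TopicModel:
    """Fitted topic model: distributions, assignment counts, hyperparameters."""

    K: int
    vocab: List[str]
    phi: np.ndarray                # K x V, rows sum to 1: p(word | topic)
    word_topic_counts: np.ndarray  # V x K assignment counts from final sample
    alpha: float
    beta: float
    n_iter: int
    seed: int

    def save(self, csv_path, json_path) -> None:
        rows = []
        for k in range(self.K):
            for v in np.nonzero(self.phi[k] > 0)[0]:
                rows.append((k, self.vocab[v], self.phi[k, v]))
        pd.DataFrame(rows, columns=["topic", "word", "p_word_given_topic"]).to_csv(
            csv_path, index=False
        )
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(
                {"K": self.K, "alpha": self.alpha, "beta": self.beta,
                 "seed": self.seed, "n_iter": self.n_iter}, fh, indent=2
            )


@njit(cache=False)
def _gibbs(word_ids, doc_ids, K, V, n_docs, alpha, beta, n_iter, seed):
    np.random.seed(seed)
    N = word_ids.shape[0]
    z = np.empty(N, dtype=np.int64)
    ndk = np.zeros((n_docs, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    for i in range(N):
        k = np.random.randint(0, K)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, word_ids[i]] += 1
        nk[k] += 1
    cum = np.empty(K)
    for _ in range(n_iter):
        for i in range(N):
            w = word_ids[i]
            d = doc_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            total = 0.0
            for kk in range(K):
                total += (nkw[kk, w] + beta) / (nk[kk] + V * beta) * (
                    ndk[d, kk] + alpha
                )
                cum[kk] = total
            u = np.random.random() * total
            knew = np.searchsorted(cum, u)
            if knew == K:  # numerical guard
                knew = K - 1
            z[i] = knew
            ndk[d, knew] += 1
            nkw[knew, w] += 1
            nk[knew] += 1
    return nkw


def fit_lda(
    documents: Sequence[Sequence[str]],
    K: int,
    alpha: float = 0.3,
    beta: float = 0.01,
    n_iter: int = 1000,
    seed: int = 0,
    stopwords: Optional[Sequence[str]] = None,
) -> TopicModel:
    """Fit LDA over tokenized documents with a collapsed Gibbs sampler.

    Deterministic given ``seed``.  ``stopwords`` (optional) are excluded from
    the vocabulary; by default every token is kept.  ``K`` may not exceed the
    vocabulary size.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    docs = [d for d in documents if len(d) > 0]
    if not docs:
        raise ValueError("documents must be non-empty")
    stop = set(stopwords or ())
    vocab_set = sorted({t for d in docs for t in d} - stop)
    V = len(vocab_set)
    if K > V:
        raise ValueError(f"K={K} exceeds vocabulary size {V}")
    vocab = {w: i for i, w in enumerate(vocab_set)}
    word_ids, doc_ids = [], []
    for d_ix, d in enumerate(docs):
        for t in d:
            if t in vocab:
                word_ids.append(vocab[t])
                doc_ids.append(d_ix)
    word_ids = np.asarray(word_ids, dtype=np.int64)
    doc_ids = np.asarray(doc_ids, dtype=np.int64)
    nkw = _gibbs(
        word_ids, doc_ids, K, V, len(docs), float(alpha), float(beta),
        int(n_iter), int(seed) % (2**31),
    )
    nk = nkw.sum(axis=1, keepdims=True)
    phi = (nkw + beta) / (nk + V * beta)
    return TopicModel(
        K=K, vocab=vocab_set, phi=phi, word_topic_counts=np.asarray(nkw).T.copy(),
        alpha=alpha, beta=beta, n_iter=n_iter, seed=seed,
    )


def topic_given_word(model: TopicModel) -> Dict[str, np.ndarray]:
    """p(topic | word) from assignment counts; words never assigned are absent."""
    out: Dict[str, np.ndarray] = {}
    for v, word in enumerate(model.vocab):
        row = model.word_topic_counts[v].astype(float)
        total = row.sum()
        if total > 0:
            out[word] = row / total
    return out


def topic_usage(
    author_counts: Dict[str, float], p_topic_word: Dict[str, np.ndarray], K: int
) -> np.ndarray:
    """p(topic | author) = sum_w p(topic|w) * p(w|author).

    ``author_counts`` are the author's word counts (or relative frequencies);
    they are renormalized over the words present in ``p_topic_word``.  An
    author sharing no word with the model vocabulary is an error.
    """
    usage = np.zeros(K)
    mass = 0.0
    for w, c in author_counts.items():
        dist = p_topic_word.get(w)
        if dist is not None and c > 0:
            usage += c * dist
            mass += c
    if mass == 0:
        raise ValueError("author shares no word with the model vocabulary")
    return usage / mass


def topic_usage_matrix(
    corpus: AuthorCorpus, model: TopicModel, prefix: str = "topic:"
) -> FeatureMatrix:
    """Authors x topics matrix of p(topic | author)."""
    ptw = topic_given_word(model)
    authors = corpus.author_ids
    values = np.zeros((len(authors), model.K))
    for i, aid in enumerate(authors):
        values[i] = topic_usage(corpus.unigram_counts[aid], ptw, model.K)
    n_used = (values > 0).sum(axis=0)
    return FeatureMatrix(
        authors, [f"{prefix}{k}" for k in range(model.K)], values, "topic_prob",
        n_authors_used=n_used,
    )


def top_words(model: TopicModel, t: int, n: int = 15) -> List[str]:
    """The n words with highest p(word|topic), ties broken lexicographically."""
    order = sorted(
        range(len(model.vocab)), key=lambda v: (-model.phi[t, v], model.vocab[v])
    )
    return [model.vocab[v] for v in order[:n]]


def load_topic_word_table(path, alpha: float = 0.3, beta: float = 0.01) -> TopicModel:
    """Import an externally estimated topic-word table (CSV word,topic,weight).

    Lets output from an external LDA tool (e.g. Mallet) be used verbatim in
    place of the in-package sampler.  Weights are treated as assignment
    counts/mass: phi rows and p(topic|word) are normalized from them.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    need = {"word", "topic", "weight"}
    if not need <= set(cols):
        raise ValueError("topic table must have word,topic,weight columns")
    words = sorted(df[cols["word"]].astype(str).unique())
    vocab = {w: i for i, w in enumerate(words)}
    K = int(df[cols["topic"]].max()) + 1
    counts = np.zeros((len(words), K))
    for _, row in df.iterrows():
        counts[vocab[str(row[cols["word"]])], int(row[cols["topic"]])] += float(
            row[cols["weight"]]
        )
    nkw = counts.T
    nk = nkw.sum(axis=1, keepdims=True)
    V = len(words)
    phi = (nkw + beta) / (nk + V * beta)
    return TopicModel(K=K, vocab=words, phi=phi, word_topic_counts=counts,
                      alpha=alpha, beta=beta, n_iter=0, seed=0)
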