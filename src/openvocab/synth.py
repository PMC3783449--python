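"""Synthetic message corpora with known, planted language-outcome structure.

The generator emulates the statistical shape of a large status-update corpus:
many short messages per author (defaults: Poisson-mean 206 messages of
Poisson-mean 20 words, about 4,100 words per author), a heavy-tailed Zipfian
background vocabulary, fixed multiword collocations emitted as intact units,
emoticon tokens, and person-level outcomes (gender 0/1, right-skewed age with
mean 23.43 and SD 8.96, five standard-normal trait scores).

Planted effects act on log-rates: a planted token's sampling weight for an
author is multiplied by ``exp(effect * z)`` where ``z`` is the author's
standardized outcome value, keeping frequencies positive and producing small
standardized association coefficients like those seen in real text.  Every
planted effect is written to a ground-truth file so recovery tests never peek
at generator internals.

The generator makes no attempt to imitate real lexical content beyond
Zipf + planted structure; vocabulary is a fixed list of common English words
followed by deterministic pronounceable pseudo-words.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .corpus import AuthorCorpus, Message, write_messages

__all__ = [
    "PlantedEffect",
    "SyntheticSpec",
    "TopicCorpusSpec",
    "SyntheticCorpus",
    "generate",
    "generate_topic_corpus",
    "background_vocabulary",
]

# Common-word core placed at the top Zipf ranks; the rest of the vocabulary
# is pseudo-words so no accidental semantics leak into tests.
_CORE_WORDS = (
    "the to and a i you it of in is that for on my me with at this so be "
    "have just not are was but all out up get like day good love time go "
    "going now what know today new work home night life one back we do "
    "can will see had great happy think when there got from her him they"
).split()

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"


def background_vocabulary(size: int) -> List[str]:
    """Deterministic vocabulary: common-word core + pronounceable pseudo-words."""
    syllables = [c + v for c, v in itertools.product(_CONSONANTS, _VOWELS)]
    rng = np.random.default_rng(20130925)  # fixed: vocabulary is not a dial
    words: List[str] = list(_CORE_WORDS)
    seen = set(words)
    pairs = list(itertools.product(range(len(syllables)), repeat=2))
    rng.shuffle(pairs)
    for i, j in pairs:
        if len(words) >= size:
            break
        w = syllables[i] + syllables[j]
        if w not in seen:
            seen.add(w)
            words.append(w)
    # three-syllable forms if two-syllable space is exhausted
    triples = itertools.product(range(len(syllables)), repeat=3)
    for i, j, k in triples:
        if len(words) >= size:
            break
        w = syllables[i] + syllables[j] + syllables[k]
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words[:size]


@dataclass(frozen=True)
class PlantedEffect:
    """A language feature whose usage rate depends on an outcome.

    ``feature`` is a token or a space-separated phrase (which must be one of
    the spec's collocations); ``effect`` is the log-rate shift per standard
    deviation of the outcome.
    """

    feature: str
    outcome: str
    effect: float


@dataclass
class SyntheticSpec:
    """Generator parameters; defaults are the emulated study conditions."""

    n_authors: int = 500
    seed: int = 0
    mean_messages: float = 206.0
    mean_words: float = 20.0
    vocab_size: int = 2000
    zipf_exponent: float = 1.1
    collocations: Dict[str, float] = field(
        default_factory=lambda: {
            "happy birthday": 2e-3,
            "new york": 1.2e-3,
            "best friend": 1.5e-3,
            "last night": 1.8e-3,
            "i love you": 1.5e-3,
        }
    )
    emoticons: Dict[str, float] = field(
        default_factory=lambda: {
            ":)": 4e-3, ":-)": 1.5e-3, ":(": 1.2e-3, "<3": 2e-3, "^_^": 6e-4,
        }
    )
    planted_effects: List[PlantedEffect] = field(default_factory=list)
    age_mean: float = 23.43
    age_sd: float = 8.96
    age_min: float = 13.0
    trait_names: Tuple[str, ...] = (
        "openness", "conscientiousness", "extraversion", "agreeableness",
        "neuroticism",
    )


@dataclass
class SyntheticCorpus:
    """In-memory generated corpus plus its ground truth."""

    messages: List[Message]
    token_lists: List[List[str]]
    outcomes: pd.DataFrame
    ground_truth: dict

    def author_corpus(self) -> AuthorCorpus:
        """Pool tokens per author directly (bypasses the text round-trip)."""
        corpus = AuthorCorpus()
        for msg, toks in zip(self.messages, self.token_lists):
            corpus.add(msg, toks)
        corpus.attach_outcomes(self.outcomes)
        return corpus

    def write(self, out_dir, message_format: str = "csv") -> None:
        os.makedirs(out_dir, exist_ok=True)
        ext = "csv" if message_format == "csv" else "jsonl"
        write_messages(
            os.path.join(out_dir, f"messages.{ext}"), self.messages,
            message_format,
        )
        self.outcomes.rename_axis("author_id").to_csv(
            os.path.join(out_dir, "outcomes.csv")
        )
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)


def _draw_outcomes(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_authors
    gender = rng.integers(0, 2, size=n).astype(float)
    m = spec.age_mean - spec.age_min
    sigma2 = math.log(1.0 + spec.age_sd**2 / m**2)
    mu = math.log(m) - sigma2 / 2.0
    age = spec.age_min + rng.lognormal(mu, math.sqrt(sigma2), size=n)
    data = {"gender": gender, "age": np.round(age, 1)}
    for t in spec.trait_names:
        data[t] = np.round(rng.normal(size=n), 4)
    ids = [f"a{i:05d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="author_id"))


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)


def generate(spec: SyntheticSpec) -> SyntheticCorpus:
    """Draw a full corpus from the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    outcomes = _draw_outcomes(spec, rng)
    vocab = background_vocabulary(spec.vocab_size)

    # sampling alphabet: background words (Zipf), emoticons, collocations
    units: List[Tuple[str, ...]] = [(w,) for w in vocab]
    weights = [1.0 / (r + 1) ** spec.zipf_exponent for r in range(len(vocab))]
    zipf_total = sum(weights)
    for tok, p in spec.emoticons.items():
        units.append((tok,))
        weights.append(p * zipf_total)
    for phrase, p in spec.collocations.items():
        units.append(tuple(phrase.split()))
        weights.append(p * zipf_total)
    base = np.asarray(weights)
    base /= base.sum()
    unit_index = {" ".join(u): j for j, u in enumerate(units)}

    # per-author log-rate shifts for planted features
    z_cols = {}
    for eff in spec.planted_effects:
        if eff.feature not in unit_index:
            raise ValueError(
                f"planted feature {eff.feature!r} not in the sampling alphabet"
            )
        if eff.outcome not in outcomes.columns:
            raise ValueError(f"planted outcome {eff.outcome!r} unknown")
        if eff.outcome not in z_cols:
            z_cols[eff.outcome] = _standardize(outcomes[eff.outcome].to_numpy())

    messages: List[Message] = []
    token_lists: List[List[str]] = []
    for i, aid in enumerate(outcomes.index):
        probs = base.copy()
        for eff in spec.planted_effects:
            j = unit_index[eff.feature]
            probs[j] *= math.exp(eff.effect * z_cols[eff.outcome][i])
        probs /= probs.sum()
        n_msgs = max(1, int(rng.poisson(spec.mean_messages)))
        lengths = np.maximum(1, rng.poisson(spec.mean_words, size=n_msgs))
        draws = rng.choice(len(units), size=int(lengths.sum()), p=probs)
        pos = 0
        for mi, L in enumerate(lengths):
            toks: List[str] = []
            for u in draws[pos : pos + L]:
                toks.extend(units[u])
            pos += L
            messages.append(Message(aid, " ".join(toks), f"m{mi:04d}"))
            token_lists.append(toks)

    ground_truth = {
        "planted_effects": [asdict(e) for e in spec.planted_effects],
        "collocations": list(spec.collocations),
        "emoticons": list(spec.emoticons),
        "vocab_size": spec.vocab_size,
        "zipf_exponent": spec.zipf_exponent,
        "seed": spec.seed,
        "n_authors": spec.n_authors,
        "mean_messages": spec.mean_messages,
        "mean_words": spec.mean_words,
    }
    return SyntheticCorpus(messages, token_lists, outcomes, ground_truth)


@dataclass
class TopicCorpusSpec:
    """Topic-structured corpus: messages mix K block vocabularies.

    Each author has a topic mixture; each message draws its own mixture
    around the author's (Dirichlet with concentration ``doc_concentration``)
    and each word picks a topic then a word from that topic's distribution.
    ``phi`` may be a known K x V matrix (with ``vocab``); by default each
    topic owns a disjoint vocabulary block.  A planted tie makes the
    ``planted_topic`` mixture weight increase with ``planted_outcome``.
    """

    n_authors: int = 200
    seed: int = 0
    K: int = 2
    block_size: int = 50
    mean_messages: float = 60.0
    mean_words: float = 12.0
    doc_concentration: float = 2.0
    mixture_noise_sd: float = 0.5
    phi: Optional[np.ndarray] = None
    vocab: Optional[List[str]] = None
    planted_topic: Optional[int] = None
    planted_outcome: Optional[str] = None
    planted_strength: float = 0.0


def generate_topic_corpus(spec: TopicCorpusSpec) -> SyntheticCorpus:
    """Draw a topic-structured corpus; deterministic given ``spec.seed``."""
    if spec.K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(spec.seed)
    out_spec = SyntheticSpec(n_authors=spec.n_authors, seed=spec.seed)
    outcomes = _draw_outcomes(out_spec, rng)

    if spec.phi is not None:
        phi = np.asarray(spec.phi, dtype=float)
        if spec.vocab is None or phi.shape != (spec.K, len(spec.vocab)):
            raise ValueError("phi requires a matching vocab of length V")
        vocab = list(spec.vocab)
    else:
        vocab = [
            f"t{k}w{j:03d}" for k in range(spec.K) for j in range(spec.block_size)
        ]
        phi = np.zeros((spec.K, len(vocab)))
        for k in range(spec.K):
            block = slice(k * spec.block_size, (k + 1) * spec.block_size)
            # mildly Zipfian within the block
            w = 1.0 / np.arange(1, spec.block_size + 1) ** 1.05
            phi[k, block] = w / w.sum()

    z = None
    if spec.planted_topic is not None:
        if spec.planted_outcome not in outcomes.columns:
            raise ValueError(f"unknown planted outcome {spec.planted_outcome!r}")
        z = _standardize(outcomes[spec.planted_outcome].to_numpy())

    messages: List[Message] = []
    token_lists: List[List[str]] = []
    theta_authors = np.zeros((spec.n_authors, spec.K))
    cum_phi = np.cumsum(phi, axis=1)
    cum_phi[:, -1] = 1.0
    for i, aid in enumerate(outcomes.index):
        logits = rng.normal(0.0, spec.mixture_noise_sd, size=spec.K)
        if z is not None:
            logits[spec.planted_topic] += spec.planted_strength * z[i]
        theta = np.exp(logits - logits.max())
        theta /= theta.sum()
        theta_authors[i] = theta
        n_msgs = max(1, int(rng.poisson(spec.mean_messages)))
        for mi in range(n_msgs):
            theta_doc = rng.dirichlet(spec.doc_concentration * theta + 1e-3)
            L = max(1, int(rng.poisson(spec.mean_words)))
            ks = rng.choice(spec.K, size=L, p=theta_doc)
            u = rng.random(L)
            word_ix = (cum_phi[ks] < u[:, None]).sum(axis=1)
            toks = [vocab[j] for j in word_ix]
            messages.append(Message(aid, " ".join(toks), f"m{mi:04d}"))
            token_lists.append(toks)

    ground_truth = {
        "K": spec.K,
        "vocab": vocab,
        "phi": phi.tolist(),
        "theta_authors": theta_authors.tolist(),
        "planted_topic": spec.planted_topic,
        "planted_outcome": spec.planted_outcome,
        "planted_strength": spec.planted_strength,
        "seed": spec.seed,
    }
    return SyntheticCorpus(messages, token_lists, outcomes, ground_truth)
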