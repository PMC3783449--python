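"""Out-of-sample predictive comparison of language feature sets.

Protocol: authors are split once into 75% train / 25% test; every candidate
feature set is built with train-only corpus statistics (PMI probabilities,
usage thresholds, topic models), reduced by PCA to half the number of
training users, and fed to a linear SVM (binary outcomes) or ridge
regression (continuous outcomes).  The regularization value is chosen on a
10% validation slice of the training set, then the model is refit on all
training authors.  Metrics: accuracy (fraction correct) for classification;
R = sqrt(max(0, 1 - SSE/SST)) on the test set for regression.

Improvement of a candidate set over a baseline is tested with a paired
bootstrap over test authors: both models' per-author predictions are
resampled together and the one-sided p-value that the candidate beats the
baseline is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.svm import LinearSVC

from .corpus import AuthorCorpus
from .features import FeatureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "split_authors",
    "reduce_pca",
    "fit_classifier",
    "fit_regressor",
    "evaluate",
    "compare_feature_sets",
]

DEFAULT_GRID = tuple(float(c) for c in np.logspace(-3, 3, 7))


@dataclass
class EvaluationReport:
    """Per (feature set, outcome) out-of-sample results."""

    outcome: str
    task: str  # "classification" | "regression"
    metric_name: str  # "accuracy" | "R"
    baseline: str
    n_train: int
    n_test: int
    metrics: Dict[str, float] = field(default_factory=dict)
    chosen_hyperparameter: Dict[str, float] = field(default_factory=dict)
    improvement_p: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature_set": name,
                "outcome": self.outcome,
                self.metric_name: value,
                "improvement_p_vs_baseline": self.improvement_p.get(name),
                "hyperparameter": self.chosen_hyperparameter.get(name),
            }
            for name, value in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def split_authors(
    author_ids: Sequence[str], test_fraction: float = 0.25, seed: int = 0
) -> Tuple[List[str], List[str]]:
    """Seeded disjoint, exhaustive train/test split; |test|=round(frac*n)."""
    ids = list(author_ids)
    if len(ids) < 8:
        raise ValueError("need at least 8 authors to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(test_fraction * len(ids)))
    test = [ids[i] for i in perm[:n_test]]
    train = [ids[i] for i in perm[n_test:]]
    return train, test


def reduce_pca(
    train_X: np.ndarray, test_X: np.ndarray, n_users_train: int
) -> Tuple[np.ndarray, np.ndarray]:
    """PCA (fit on train only) to half the number of training users.

    Components are capped by the feature count and by the PCA rank limit
    (n_samples - 1 with centering).  Centered, not whitened.
    """
    n_comp = min(
        n_users_train // 2, train_X.shape[1], train_X.shape[0] - 1
    )
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca.fit_transform(train_X), pca.transform(test_X)


def _validation_split(n: int, seed: int) -> Tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(0.1 * n)))
    return perm[n_val:], perm[:n_val]


def fit_classifier(
    train_X: np.ndarray,
    train_y: np.ndarray,
    grid: Sequence[float] = DEFAULT_GRID,
    seed: int = 0,
):
    """Linear SVM with regularization chosen on a 10% validation slice."""
    y = np.asarray(train_y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    fit_ix, val_ix = _validation_split(len(y), seed)
    if len(np.unique(y[fit_ix])) < 2:
        raise ValueError("validation split left a single class in training")
    best_c, best_score = None, -np.inf
    for c in grid:
        clf = LinearSVC(C=c, dual=False, max_iter=20000)
        clf.fit(train_X[fit_ix], y[fit_ix])
        score = float(np.mean(clf.predict(train_X[val_ix]) == y[val_ix]))
        if score > best_score:
            best_c, best_score = c, score
    model = LinearSVC(C=best_c, dual=False, max_iter=20000)
    model.fit(train_X, y)
    model.chosen_hyperparameter_ = best_c
    return model


def fit_regressor(
    train_X: np.ndarray,
    train_y: np.ndarray,
    grid: Sequence[float] = DEFAULT_GRID,
    seed: int = 0,
):
    """Ridge regression with the same 10%-validation protocol."""
    y = np.asarray(train_y, dtype=float)
    if y.std(ddof=0) == 0:
        raise ValueError("outcome has zero variance")
    fit_ix, val_ix = _validation_split(len(y), seed)
    best_a, best_score = None, -np.inf
    for a in grid:
        reg = Ridge(alpha=a)
        reg.fit(train_X[fit_ix], y[fit_ix])
        pred = reg.predict(train_X[val_ix])
        score = -float(np.mean((pred - y[val_ix]) ** 2))
        if score > best_score:
            best_a, best_score = a, score
    model = Ridge(alpha=best_a)
    model.fit(train_X, y)
    model.chosen_hyperparameter_ = best_a
    return model


def evaluate(model, test_X: np.ndarray, test_y: np.ndarray, task: str) -> float:
    """Accuracy for classification; R = sqrt(max(0, 1 - SSE/SST)) else."""
    if len(test_y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test_X)
    return _metric_from_predictions(pred, np.asarray(test_y, dtype=float), task)


def _metric_from_predictions(pred, truth, task: str) -> float:
    if task == "classification":
        return float(np.mean(pred == truth))
    sst = float(np.sum((truth - truth.mean()) ** 2))
    if sst == 0:
        raise ValueError("test outcome has zero variance (SST = 0)")
    sse = float(np.sum((truth - pred) ** 2))
    return math.sqrt(max(0.0, 1.0 - sse / sst))


def _paired_bootstrap_p(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    truth: np.ndarray,
    task: str,
    n_boot: int,
    seed: int,
) -> float:
    """One-sided p that candidate a beats baseline b, paired over authors."""
    rng = np.random.default_rng(seed)
    n = len(truth)
    count = 0
    for _ in range(n_boot):
        ix = rng.integers(0, n, size=n)
        try:
            ma = _metric_from_predictions(pred_a[ix], truth[ix], task)
            mb = _metric_from_predictions(pred_b[ix], truth[ix], task)
        except ValueError:  # degenerate resample (constant truth)
            continue
        if ma <= mb:
            count += 1
    return (1 + count) / (n_boot + 1)


class FeatureSetBuilder:
    """Interface: fit on training authors, transform any author subset."""

    def fit(self, corpus: AuthorCorpus) -> "FeatureSetBuilder":
        raise NotImplementedError

    def transform(self, corpus: AuthorCorpus) -> FeatureMatrix:
        raise NotImplementedError


class NgramFeatureSet(FeatureSetBuilder):
    def __init__(self, **kwargs):
        from .features import NgramVectorizer

        kwargs.setdefault("prefix", "ngram:")
        self._vec = NgramVectorizer(**kwargs)

    def fit(self, corpus):
        self._vec.fit(corpus)
        return self

    def transform(self, corpus):
        return self._vec.transform(corpus)


class TopicFeatureSet(FeatureSetBuilder):
    def __init__(self, K=25, alpha=0.3, beta=0.01, n_iter=300, seed=0):
        self.params = dict(K=K, alpha=alpha, beta=beta, n_iter=n_iter, seed=seed)

    def fit(self, corpus):
        from .topics import fit_lda

        docs = [m for aid in corpus.author_ids for m in corpus.messages[aid]]
        self.model_ = fit_lda(docs, **self.params)
        return self

    def transform(self, corpus):
        from .topics import topic_usage_matrix

        return topic_usage_matrix(corpus, self.model_)


class LexiconFeatureSet(FeatureSetBuilder):
    def __init__(self, lexicon):
        self.lexicon = lexicon

    def fit(self, corpus):
        return self

    def transform(self, corpus):
        from .lexica import lexicon_feature_matrix

        return lexicon_feature_matrix(corpus, self.lexicon, prefix="cat:")


def compare_feature_sets(
    corpus: AuthorCorpus,
    outcomes: pd.DataFrame,
    outcome: str,
    task: str,
    builders: Dict[str, FeatureSetBuilder],
    set_specs: Dict[str, Sequence[str]],
    baseline: str,
    test_fraction: float = 0.25,
    seed: int = 0,
    n_boot: int = 2000,
    grid: Sequence[float] = DEFAULT_GRID,
) -> EvaluationReport:
    """Evaluate feature sets (and unions) under one identical split.

    ``builders`` are the base extractors; ``set_specs`` maps a set name to
    the base names whose matrices are column-concatenated (deduplicated)
    before PCA.  ``baseline`` names the set every other set is bootstrap-
    compared against.  Test authors never influence feature fitting, PCA,
    scaling or hyperparameter choice.
    """
    if len(set_specs) < 2:
        raise ValueError("need at least two feature sets to compare")
    if baseline not in set_specs:
        raise ValueError(f"baseline {baseline!r} not among the feature sets")
    ids = [a for a in corpus.author_ids if a in outcomes.index
           and pd.notna(outcomes.loc[a, outcome])]
    train_ids, test_ids = split_authors(ids, test_fraction, seed)
    train_corpus = corpus.subset(train_ids)
    test_corpus = corpus.subset(test_ids)
    y_train = outcomes.loc[train_ids, outcome].to_numpy(dtype=float)
    y_test = outcomes.loc[test_ids, outcome].to_numpy(dtype=float)

    base_mats: Dict[str, Tuple[FeatureMatrix, FeatureMatrix]] = {}
    for name, builder in builders.items():
        builder.fit(train_corpus)
        base_mats[name] = (
            builder.transform(train_corpus), builder.transform(test_corpus)
        )

    report = EvaluationReport(
        outcome=outcome,
        task=task,
        metric_name="accuracy" if task == "classification" else "R",
        baseline=baseline,
        n_train=len(train_ids),
        n_test=len(test_ids),
    )
    predictions: Dict[str, np.ndarray] = {}
    for set_name, parts in set_specs.items():
        tr, te = base_mats[parts[0]]
        for p in parts[1:]:
            tr = tr.hstack(base_mats[p][0])
            te = te.hstack(base_mats[p][1])
        Xtr, Xte = reduce_pca(tr.values, te.values, len(train_ids))
        if task == "classification":
            model = fit_classifier(Xtr, y_train, grid, seed)
        else:
            model = fit_regressor(Xtr, y_train, grid, seed)
        predictions[set_name] = model.predict(Xte)
        report.metrics[set_name] = _metric_from_predictions(
            predictions[set_name], y_test, task
        )
        report.chosen_hyperparameter[set_name] = model.chosen_hyperparameter_
        log.info("%s / %s: %s = %.4f", set_name, outcome,
                 report.metric_name, report.metrics[set_name])
    for set_name in set_specs:
        if set_name == baseline:
            continue
        report.improvement_p[set_name] = _paired_bootstrap_p(
            predictions[set_name], predictions[baseline], y_test, task,
            n_boot, seed + 1,
        )
    return report
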