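"""Mass-univariate differential language analysis.

Each language feature is regressed on independently: the outcome is modeled
by OLS on [feature, covariates, intercept] with every regressor and the
outcome z-scored, so the feature's coefficient is a standardized beta (equal
to the Pearson correlation when there are no covariates).  Significance is
two-tailed from the t distribution with n - p - 1 degrees of freedom and is
corrected over the whole feature family, either Bonferroni (threshold
``family_alpha / m``) or Benjamini-Hochberg step-up FDR.

``run_dla`` vectorizes the per-feature regressions through the
Frisch-Waugh-Lovell identity (residualize outcome and features on the
covariates once); ``fit_feature_association`` is the single-feature
reference route via statsmodels, and the two agree to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureMatrix

log = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "CorrectionSpec",
    "fit_feature_association",
    "run_dla",
    "bonferroni_threshold",
    "benjamini_hochberg",
    "power_analysis",
]


@dataclass
class AssociationResult:
    """One (feature, outcome) association."""

    feature_id: str
    outcome_name: str
    beta_std: float
    p_value: float
    n: int
    corpus_frequency: Optional[float] = None
    significant: bool = False


@dataclass(frozen=True)
class CorrectionSpec:
    """Multiple-testing control over one outcome's feature family."""

    method: str = "bonferroni"  # or "benjamini_hochberg"
    family_alpha: float = 0.001

    def __post_init__(self):
        if self.method not in ("bonferroni", "benjamini_hochberg"):
            raise ValueError(f"unknown correction method {self.method!r}")
        if not 0 < self.family_alpha < 1:
            raise ValueError("family_alpha must be in (0, 1)")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance variable")
    return (x - x.mean()) / sd


def fit_feature_association(
    feature_values: np.ndarray,
    outcome_values: np.ndarray,
    covariate_matrix: Optional[np.ndarray] = None,
    feature_id: str = "feature",
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Covariate-adjusted standardized beta for one feature (statsmodels OLS).

    Rows with a missing outcome, feature or covariate value are dropped
    pairwise.  Zero-variance feature or outcome raises ``ValueError``.
    """
    import statsmodels.api as sm

    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(outcome_values, dtype=float)
    C = (
        np.empty((len(y), 0))
        if covariate_matrix is None
        else np.asarray(covariate_matrix, dtype=float).reshape(len(y), -1)
    )
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    n, p = len(y), 1 + C.shape[1]
    if n < p + 2:
        raise ValueError(f"need n >= {p + 2} complete observations, have {n}")
    design = np.column_stack(
        [_zscore(x)] + [_zscore(C[:, j]) for j in range(C.shape[1])]
    )
    model = sm.OLS(_zscore(y), sm.add_constant(design, prepend=False)).fit()
    return AssociationResult(
        feature_id=feature_id,
        outcome_name=outcome_name,
        beta_std=float(model.params[0]),
        p_value=float(model.pvalues[0]),
        n=n,
    )


def bonferroni_threshold(family_alpha: float, m: int) -> float:
    """Per-test threshold ``family_alpha / m`` (e.g. 0.001 / 20000 = 5e-8)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def benjamini_hochberg(p_values: Sequence[float], q: float) -> np.ndarray:
    """Step-up FDR: reject ranks <= the largest i with p(i) <= i*q/m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    passed = np.nonzero(p[order] <= (np.arange(1, m + 1) * q / m))[0]
    reject = np.zeros(m, dtype=bool)
    if len(passed):
        reject[order[: passed[-1] + 1]] = True
    return reject


def _mass_univariate(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, List[int]]:
    """Standardized betas and two-tailed p for every column of X at once.

    Frisch-Waugh: residualize z-scored y and X on [1, covariates]; the
    feature coefficient and its t-test from the full per-feature OLS follow
    from the residual cross-products with df = n - ncov - 2.  Returns
    (beta, p, skipped) where ``skipped`` lists zero-variance columns.
    """
    n, m = X.shape
    sd = X.std(axis=0, ddof=0)
    skipped = list(np.nonzero(sd == 0)[0])
    good = sd > 0
    Xz = np.zeros_like(X)
    Xz[:, good] = (X[:, good] - X[:, good].mean(axis=0)) / sd[good]
    yz = _zscore(y)
    D = np.column_stack([np.ones(n)] + [_zscore(C[:, j]) for j in range(C.shape[1])])
    Q, _ = np.linalg.qr(D)
    yr = yz - Q @ (Q.T @ yz)
    Xr = Xz - Q @ (Q.T @ Xz)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    sxy = Xr.T @ yr
    syy = float(yr @ yr)
    df = n - C.shape[1] - 2
    beta = np.zeros(m)
    pvals = np.ones(m)
    ok = good & (sxx > 0)
    beta[ok] = sxy[ok] / sxx[ok]
    sse = syy - beta[ok] * sxy[ok]
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx[ok])
        t = np.where(
            se > 0,
            np.divide(beta[ok], se, out=np.zeros_like(se), where=se > 0),
            np.where(beta[ok] == 0, 0.0, np.inf),
        )
    pvals[ok] = 2 * sps.t.sf(np.abs(t), df)
    return beta, pvals, skipped


def run_dla(
    matrix: FeatureMatrix,
    outcomes: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = (),
    correction: CorrectionSpec = CorrectionSpec(),
) -> List[AssociationResult]:
    """One independent covariate-adjusted regression per feature.

    Authors missing the outcome or any covariate are dropped (pairwise,
    per-outcome deletion).  The correction is applied over the feature family
    for this outcome; results are ranked significant-first by |beta|
    descending.  Zero-variance features are skipped with a log entry and
    reported with p = 1.
    """
    if len(matrix.features) == 0:
        raise ValueError("empty feature set")
    if outcome not in outcomes.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    for c in covariates:
        if c not in outcomes.columns:
            raise ValueError(f"unknown covariate {c!r}")
    sub = outcomes.reindex(matrix.authors)
    needed = sub[[outcome, *covariates]]
    keep = needed.notna().all(axis=1).to_numpy()
    X = matrix.values[keep]
    y = needed[outcome].to_numpy(dtype=float)[keep]
    C = needed[list(covariates)].to_numpy(dtype=float)[keep].reshape(keep.sum(), -1)
    n = int(keep.sum())
    if n < C.shape[1] + 3:
        raise ValueError(f"too few complete authors (n={n}) for the model")
    beta, pvals, skipped = _mass_univariate(X, y, C)
    if skipped:
        log.warning(
            "skipped %d zero-variance feature(s): %s",
            len(skipped),
            [matrix.features[j] for j in skipped[:10]],
        )
    m = len(matrix.features)
    if correction.method == "bonferroni":
        sig = pvals < bonferroni_threshold(correction.family_alpha, m)
    else:
        sig = benjamini_hochberg(pvals, correction.family_alpha)
    freq = matrix.corpus_frequency
    results = [
        AssociationResult(
            feature_id=matrix.features[j],
            outcome_name=outcome,
            beta_std=float(beta[j]),
            p_value=float(pvals[j]),
            n=n,
            corpus_frequency=None if freq is None else float(freq[j]),
            significant=bool(sig[j]) and j not in skipped,
        )
        for j in range(m)
    ]
    results.sort(key=lambda r: (not r.significant, -abs(r.beta_std), r.feature_id))
    return results


def results_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "outcome": [r.outcome_name for r in results],
            "beta_std": [r.beta_std for r in results],
            "p": [r.p_value for r in results],
            "n": [r.n for r in results],
            "corpus_frequency": [r.corpus_frequency for r in results],
            "significant": [r.significant for r in results],
        }
    )


def power_analysis(
    corpus,
    outcomes: pd.DataFrame,
    outcome: str,
    sample_sizes: Sequence[int],
    reps: int = 10,
    correction: CorrectionSpec = CorrectionSpec("benjamini_hochberg", 0.001),
    covariates: Sequence[str] = (),
    seed: int = 0,
    vectorizer_factory=None,
) -> pd.DataFrame:
    """Mean count of significant features at reduced author sample sizes.

    For each size, authors are drawn without replacement, the usage-filtered
    feature set is recomputed on the subsample, and the analysis is re-run;
    counts are averaged over ``reps`` seeded draws.
    """
    from .features import NgramVectorizer

    if vectorizer_factory is None:
        vectorizer_factory = NgramVectorizer
    rng = np.random.default_rng(seed)
    all_ids = np.asarray(corpus.author_ids)
    rows = []
    for size in sample_sizes:
        if size > len(all_ids):
            raise ValueError(f"sample size {size} exceeds corpus ({len(all_ids)})")
        counts = []
        for _ in range(reps):
            ids = list(rng.choice(all_ids, size=size, replace=False))
            sub = corpus.subset(ids)
            mat = vectorizer_factory().fit_transform(sub)
            res = run_dla(mat, outcomes, outcome, covariates, correction)
            counts.append(sum(r.significant for r in res))
        rows.append((size, float(np.mean(counts))))
    return pd.DataFrame(rows, columns=["sample_size", "mean_significant"])
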