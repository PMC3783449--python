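import itertools

import numpy as np
import pandas as pd
import pytest

from openvocab.features import FeatureMatrix
from openvocab.stats import (
    CorrectionSpec,
    benjamini_hochberg,
    bonferroni_threshold,
    fit_feature_association,
    run_dla,
)


def _matrix(values, authors=None, features=None, **kw):
    values = np.asarray(values, dtype=float)
    authors = authors or [f"a{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(authors, features, values, "anscombe_relfreq", **kw)


class TestFitFeatureAssociation:
    def test_outcome_identical_to_feature(self):
        x = np.arange(30, dtype=float)
        res = fit_feature_association(x, x.copy())
        assert res.beta_std == pytest.approx(1.0, abs=1e-9)
        assert res.p_value < 1e-10

    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            res = fit_feature_association(x, y)
            r = np.corrcoef(x, y)[0, 1]
            assert abs(res.beta_std - r) < 1e-10

    def test_covariate_absorbs_confounded_outcome(self):
        rng = np.random.default_rng(5)
        n = 1000
        c = rng.normal(size=n)
        x = rng.normal(size=n)  # independent of outcome
        y = c.copy()
        res = fit_feature_association(x, y, c.reshape(-1, 1))
        assert abs(res.beta_std) < 0.1

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            x = rng.normal(size=50)
            y = rng.normal(size=50)
            ps.append(fit_feature_association(x, y).p_value)
        ps = np.asarray(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.15

    def test_missing_rows_dropped_pairwise(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, np.nan])
        res = fit_feature_association(x, y)
        assert res.n == 7

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_feature_association(np.ones(20), np.arange(20.0))


class TestCorrections:
    def test_bonferroni_paper_inputs(self):
        assert bonferroni_threshold(0.001, 20000) == pytest.approx(5e-8, abs=0)

    def test_bonferroni_edges(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.001, 10) == pytest.approx(1e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.001, 0)

    def test_bh_hand_example(self):
        flags = benjamini_hochberg([0.0001, 0.002, 0.03, 0.9], 0.05)
        assert flags.sum() == 3 and not flags[3]

    def test_bh_all_ones_rejects_nothing(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0], 0.05).sum() == 0

    def test_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(1, 11))
            p = np.round(rng.uniform(size=m), 3)
            q = 0.1
            # brute force: largest i with p_(i) <= i*q/m, reject the i smallest
            srt = np.sort(p)
            best = 0
            for i in range(1, m + 1):
                if srt[i - 1] <= i * q / m:
                    best = i
            expect = p <= (srt[best - 1] if best else -1)
            got = benjamini_hochberg(p, q)
            assert got.sum() == expect.sum()
            np.testing.assert_array_equal(np.sort(p[got]), np.sort(p[expect]))

    def test_bh_dominates_bonferroni(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.uniform(size=30) ** 2
            q = 0.05
            bonf = p < bonferroni_threshold(q, len(p))
            bh = benjamini_hochberg(p, q)
            assert np.all(bh[bonf])

    def test_statsmodels_agreement(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(size=200) ** 3
        ours = benjamini_hochberg(p, 0.05)
        theirs = multipletests(p, 0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(ours, theirs)


class TestRunDla:
    def _outcomes(self, n, rng, planted=None):
        df = pd.DataFrame(
            {
                "gender": rng.integers(0, 2, n).astype(float),
                "age": rng.uniform(16, 60, n),
                "trait": rng.normal(size=n),
            },
            index=pd.Index([f"a{i}" for i in range(n)], name="author_id"),
        )
        return df

    def test_matches_single_feature_route_exactly(self):
        rng = np.random.default_rng(12)
        n, m = 60, 8
        X = rng.normal(size=(n, m))
        out = self._outcomes(n, rng)
        mat = _matrix(X)
        results = {
            r.feature_id: r
            for r in run_dla(mat, out, "trait", ["gender", "age"])
        }
        C = out[["gender", "age"]].to_numpy()
        for j in range(m):
            ref = fit_feature_association(X[:, j], out["trait"].to_numpy(), C)
            got = results[f"f{j}"]
            assert got.beta_std == pytest.approx(ref.beta_std, abs=1e-10)
            assert got.p_value == pytest.approx(ref.p_value, abs=1e-10, rel=1e-8)

    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(13)
        n, m = 500, 50
        X = rng.normal(size=(n, m))
        out = self._outcomes(n, rng)
        X[:, 17] += 0.8 * out["trait"].to_numpy()
        results = run_dla(_matrix(X), out, "trait")
        assert results[0].feature_id == "f17"
        assert results[0].significant

    def test_single_feature_family_threshold_is_alpha(self):
        rng = np.random.default_rng(14)
        n = 100
        out = self._outcomes(n, rng)
        x = out["trait"].to_numpy() + rng.normal(scale=0.9, size=n)
        res = run_dla(_matrix(x.reshape(-1, 1)), out, "trait",
                      correction=CorrectionSpec("bonferroni", 0.001))
        assert res[0].significant == (res[0].p_value < 0.001)

    def test_invariant_to_row_and_column_order(self):
        rng = np.random.default_rng(15)
        n, m = 40, 6
        X = rng.normal(size=(n, m))
        out = self._outcomes(n, rng)
        base = run_dla(_matrix(X), out, "trait", ["gender"])
        perm_rows = rng.permutation(n)
        perm_cols = rng.permutation(m)
        mat2 = _matrix(
            X[perm_rows][:, perm_cols],
            authors=[f"a{i}" for i in perm_rows],
            features=[f"f{j}" for j in perm_cols],
        )
        shuffled = run_dla(mat2, out, "trait", ["gender"])
        a = {r.feature_id: r.beta_std for r in base}
        b = {r.feature_id: r.beta_std for r in shuffled}
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-10)

    def test_missing_outcome_authors_dropped(self):
        rng = np.random.default_rng(16)
        out = self._outcomes(30, rng)
        out.loc["a3", "trait"] = np.nan
        res = run_dla(_matrix(rng.normal(size=(30, 3))), out, "trait")
        assert res[0].n == 29

    def test_zero_variance_feature_skipped_not_significant(self):
        rng = np.random.default_rng(17)
        out = self._outcomes(30, rng)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 5.0
        res = {r.feature_id: r for r in run_dla(_matrix(X), out, "trait")}
        assert res["f1"].p_value == 1.0 and not res["f1"].significant

    def test_empty_feature_set_rejected(self):
        rng = np.random.default_rng(18)
        out = self._outcomes(10, rng)
        with pytest.raises(ValueError, match="empty"):
            run_dla(_matrix(np.empty((10, 0))), out, "trait")

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(19)
        alpha = 0.05
        hits = 0
        reps = 100
        for _ in range(reps):
            X = rng.normal(size=(50, 20))
            out = self._outcomes(50, rng)
            res = run_dla(_matrix(X), out, "trait",
                          correction=CorrectionSpec("bonferroni", alpha))
            hits += any(r.significant for r in res)
        assert hits / reps <= alpha * 3
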