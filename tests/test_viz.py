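import json

import numpy as np
import pytest

from openvocab.stats import AssociationResult
from openvocab.viz import (
    loess_trend,
    make_entries,
    prune_phrases,
    prune_topics,
    render_cloud,
    render_topic_panel,
)


def _res(feature, beta, significant=True):
    return AssociationResult(feature, "o", beta, 1e-9, 100, None, significant)


class TestPrunePhrases:
    FREQ = {"the": 1000.0, "day": 500.0, "beautiful": 50.0}

    def test_worked_example_day_beautiful_the(self):
        ranked = [_res("day", 0.3), _res("beautiful_day", 0.25), _res("the_day", 0.2)]
        kept = [r.feature_id for r in prune_phrases(ranked, self.FREQ)]
        assert kept == ["day", "beautiful_day"]

    def test_disjoint_features_all_retained(self):
        ranked = [_res("sun", 0.3), _res("rain_cloud", 0.2)]
        assert len(prune_phrases(ranked, {"sun": 9, "rain": 2, "cloud": 3})) == 2

    def test_subset_order_preserving_idempotent(self):
        ranked = [_res("day", 0.3), _res("the_day", 0.25), _res("beautiful_day", 0.2)]
        once = prune_phrases(ranked, self.FREQ)
        assert [r.feature_id for r in once] == ["day", "beautiful_day"]
        assert prune_phrases(once, self.FREQ) == once
        assert all(r in ranked for r in once)

    def test_single_words_always_retained(self):
        ranked = [_res("the_day", 0.3), _res("the", 0.2), _res("day", 0.1)]
        kept = [r.feature_id for r in prune_phrases(ranked, self.FREQ)]
        assert "the" in kept and "day" in kept


class TestPruneTopics:
    def _tops(self, n_shared):
        shared = [f"s{i}" for i in range(n_shared)]
        return {
            "t0": shared + [f"a{i}" for i in range(15 - n_shared)],
            "t1": shared + [f"b{i}" for i in range(15 - n_shared)],
        }

    def test_four_of_fifteen_drops_lower(self):
        res = [_res("t0", 0.5), _res("t1", 0.4)]
        kept = prune_topics(res, self._tops(4))
        assert [r.feature_id for r in kept] == ["t0"]

    def test_three_of_fifteen_keeps_both(self):
        res = [_res("t0", 0.5), _res("t1", 0.4)]
        assert len(prune_topics(res, self._tops(3))) == 2

    def test_identical_topics_keep_higher_only(self):
        res = [_res("t0", 0.5), _res("t1", 0.4)]
        kept = prune_topics(res, self._tops(15))
        assert [r.feature_id for r in kept] == ["t0"]


class TestRenderCloud:
    FREQ = {"alpha": 100.0, "beta": 10.0, "gamma": 500.0}

    def test_size_monotone_in_beta(self, tmp_path):
        res = [_res("alpha", 0.2), _res("beta", 0.1)]
        entries = render_cloud(res, self.FREQ, tmp_path / "c.svg", seed=1)
        by = {e.text: e for e in entries}
        assert by["alpha"].font_size > by["beta"].font_size

    def test_non_significant_rejected(self, tmp_path):
        res = [_res("alpha", 0.2), _res("beta", 0.1, significant=False)]
        with pytest.raises(ValueError, match="significant"):
            render_cloud(res, self.FREQ, tmp_path / "c.svg")

    def test_empty_results_advise(self, tmp_path):
        with pytest.raises(ValueError, match="threshold|alpha"):
            render_cloud([], self.FREQ, tmp_path / "c.svg")

    def test_same_seed_byte_identical_svg(self, tmp_path):
        res = [_res("alpha", 0.2), _res("beta", 0.1), _res("gamma", 0.05)]
        render_cloud(res, self.FREQ, tmp_path / "a.svg", seed=9)
        render_cloud(res, self.FREQ, tmp_path / "b.svg", seed=9)
        assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()

    def test_sidecar_lists_every_feature(self, tmp_path):
        res = [_res("alpha", 0.2), _res("beta", -0.1)]
        render_cloud(res, self.FREQ, tmp_path / "c.svg", seed=2)
        side = json.loads((tmp_path / "c.svg.json").read_text())
        assert {s["feature"] for s in side} == {"alpha", "beta"}
        assert {s["polarity"] for s in side} == {1, -1}

    def test_no_overlapping_boxes(self, tmp_path):
        res = [_res(f"word{i}", 0.3 - 0.01 * i) for i in range(12)]
        freq = {f"word{i}": float(i + 1) for i in range(12)}
        entries = render_cloud(res, freq, tmp_path / "c.svg", seed=3)
        boxes = []
        for e in entries:
            w, h = 0.6 * e.font_size * len(e.text), 1.15 * e.font_size
            boxes.append((e.x - w / 2, e.y - h / 2, e.x + w / 2, e.y + h / 2))
        for i in range(len(boxes)):
            for j in range(i + 1, len(boxes)):
                a, b = boxes[i], boxes[j]
                assert not (a[0] < b[2] and a[2] > b[0] and a[1] < b[3] and a[3] > b[1])

    def test_png_written(self, tmp_path):
        res = [_res("alpha", 0.2)]
        render_cloud(res, self.FREQ, tmp_path / "c.png", fmt="png", seed=1)
        assert (tmp_path / "c.png").stat().st_size > 0


class TestRenderTopicPanel:
    def _topic_inputs(self, n_topics):
        tres = [_res(f"t{k}", 0.5 - 0.02 * k) for k in range(n_topics)]
        tops = {f"t{k}": [f"w{k}_{i}" for i in range(15)] for k in range(n_topics)}
        weights = {
            f"t{k}": {f"w{k}_{i}": 1.0 / (i + 1) for i in range(15)}
            for k in range(n_topics)
        }
        return tres, tops, weights

    def test_at_most_six_topics_shown(self, tmp_path):
        tres, tops, weights = self._topic_inputs(8)
        words = [_res("hello", 0.3)]
        render_topic_panel(words, {"hello": 5.0}, tres, tops, weights,
                           tmp_path / "p.svg", seed=4)
        side = json.loads((tmp_path / "p.svg.json").read_text())
        assert side["topics"] == [f"t{k}" for k in range(6)]

    def test_zero_topics_warns_and_renders_central(self, tmp_path):
        words = [_res("hello", 0.3)]
        with pytest.warns(UserWarning, match="central"):
            render_topic_panel(words, {"hello": 5.0}, [], {}, {},
                               tmp_path / "p.svg", seed=4)
        assert (tmp_path / "p.svg").exists()


class TestLoessTrend:
    def test_global_line_reproduced(self):
        rng = np.random.default_rng(1)
        age = np.sort(rng.uniform(20, 50, 150))
        y = 2.0 * age
        grid = np.linspace(25, 45, 20)
        curve = loess_trend(y, age, grid=grid, span=0.6)
        expected = (2.0 * grid - y.mean()) / y.std()
        np.testing.assert_allclose(curve.fitted, expected, atol=1e-6)

    def test_zero_variance_feature_rejected(self):
        age = np.linspace(20, 50, 30)
        with pytest.raises(ValueError, match="variance"):
            loess_trend(np.ones(30), age)

    def test_grid_outside_range_rejected(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(20, 50, 40)
        with pytest.raises(ValueError, match="range"):
            loess_trend(rng.normal(size=40), age, grid=np.array([10.0, 30.0]))

    def test_neutral_covariate_equals_group_average_for_linear_model(self):
        # y linear in age and gender with balanced genders:
        # prediction at gender mean (0.5) == average of per-gender predictions
        rng = np.random.default_rng(3)
        n = 200
        age = rng.uniform(20, 50, n)
        gender = np.tile([0.0, 1.0], n // 2)
        y = 1.5 * age + 4.0 * gender
        grid = np.linspace(25, 45, 7)
        curve = loess_trend(y, age, gender, grid=grid, span=0.8)
        zy = (y - y.mean()) / y.std()
        # direct WLS oracle evaluated at gender 0 and 1, averaged
        from numpy.linalg import lstsq

        for gi, x0 in enumerate(grid):
            d = np.abs(age - x0)
            k = max(int(np.ceil(0.8 * n)), 3)
            h = np.partition(d, k - 1)[k - 1]
            w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
            D = np.column_stack([np.ones(n), age - x0, gender])
            coef = lstsq((D * w[:, None]).T @ D, (D * w[:, None]).T @ zy,
                         rcond=None)[0]
            avg = (coef[0] + (coef[0] + coef[2])) / 2
            assert curve.fitted[gi] == pytest.approx(avg, abs=1e-8)
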