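"""Correlation-scaled word clouds, redundancy pruning, and LOESS age trends.

Unlike frequency-scaled clouds, word size here encodes the strength of the
(covariate-adjusted, standardized) association and color encodes corpus
frequency: larger words are more distinguishing, darker words more common.
Only features surviving the multiple-testing correction may be rendered.

Redundancy pruning keeps clouds readable: scanning features from strongest to
weakest association, a phrase that shares a word with an already-kept feature
is retained only when its remaining words are rarer (hence more informative)
than the shared word — so "beautiful day" survives alongside "day" while
"the day" is dropped.  Topic clouds are deduplicated by top-word overlap:
a lower-ranking topic is hidden when more than 25% of its top 15 words
already appear in a kept topic's top 15.

Layout is a seeded Archimedean-spiral placement with rectangle collision;
aesthetics are not part of the contract, byte-determinism of the SVG is.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stats import AssociationResult

__all__ = [
    "CloudEntry",
    "TrendCurve",
    "prune_phrases",
    "prune_topics",
    "render_cloud",
    "render_topic_panel",
    "loess_trend",
]

_COLOR_RAMP = ["#c6c6c6", "#8a8a8a", "#4d4d8f", "#1a1a4e"]  # light -> dark


@dataclass
class CloudEntry:
    """One rendered feature: text, size weight in (0,1], frequency bin, sign."""

    text: str
    size_weight: float
    color_bin: int
    polarity: int
    x: float = 0.0
    y: float = 0.0
    font_size: float = 0.0


@dataclass
class TrendCurve:
    """LOESS-fitted standardized frequency over a strictly increasing grid."""

    grid: np.ndarray
    fitted: np.ndarray
    span: float
    covariate_value: float


def _words_of(feature: str) -> List[str]:
    return feature.split("_")


def prune_phrases(
    results: Sequence[AssociationResult],
    word_frequencies: Dict[str, float],
) -> List[AssociationResult]:
    """Drop phrases whose extra words add no information over kept features.

    ``results`` must already be ranked by |beta| descending.  Single words
    are always retained.  A phrase sharing >= 1 word with any previously
    retained feature is kept only if each of its non-shared words has
    strictly lower corpus frequency than the least frequent shared word;
    phrases sharing nothing are kept.  Deterministic, order-preserving,
    idempotent.
    """
    retained: List[AssociationResult] = []
    retained_words: set = set()
    for res in results:
        words = _words_of(res.feature_id)
        if len(words) == 1:
            retained.append(res)
            retained_words.update(words)
            continue
        shared = [w for w in words if w in retained_words]
        if not shared:
            retained.append(res)
            retained_words.update(words)
            continue
        bar = min(word_frequencies.get(w, 0.0) for w in shared)
        extra = [w for w in words if w not in retained_words]
        if extra and all(word_frequencies.get(w, 0.0) < bar for w in extra):
            retained.append(res)
            retained_words.update(words)
    return retained


def prune_topics(
    results: Sequence[AssociationResult],
    top15: Dict[str, Sequence[str]],
    max_overlap_fraction: float = 0.25,
) -> List[AssociationResult]:
    """Hide a topic when > 25% of its top-15 words repeat a kept topic's.

    With 15-word lists the threshold is strict: 4 shared words (26.7%)
    triggers the drop, 3 (20%) does not.
    """
    retained: List[AssociationResult] = []
    for res in results:
        words = set(top15[res.feature_id])
        limit = max_overlap_fraction * len(top15[res.feature_id])
        if all(
            len(words & set(top15[r.feature_id])) <= limit for r in retained
        ):
            retained.append(res)
    return retained


# ---------------------------------------------------------------------------
# cloud layout and rendering
# ---------------------------------------------------------------------------

def _text_box(text: str, font_size: float) -> Tuple[float, float]:
    # fixed approximate glyph metrics keep layout renderer-independent
    return 0.6 * font_size * len(text), 1.15 * font_size


def _spiral_layout(
    entries: List[CloudEntry], seed: int, min_font: float, max_font: float
) -> Tuple[float, float]:
    """Place entries on an Archimedean spiral without overlaps (seeded)."""
    rng = np.random.default_rng(seed)
    placed: List[Tuple[float, float, float, float]] = []
    for e in entries:
        e.font_size = min_font + (max_font - min_font) * e.size_weight
        w, h = _text_box(e.text, e.font_size)
        theta0 = float(rng.uniform(0, 2 * math.pi))
        t = 0.0
        while True:
            r = 2.0 * t
            x = r * math.cos(theta0 + t)
            y = r * math.sin(theta0 + t)
            box = (x - w / 2, y - h / 2, x + w / 2, y + h / 2)
            if not any(
                box[0] < p[2] and box[2] > p[0] and box[1] < p[3] and box[3] > p[1]
                for p in placed
            ):
                e.x, e.y = x, y
                placed.append(box)
                break
            t += 0.15
    xs0 = min(p[0] for p in placed)
    ys0 = min(p[1] for p in placed)
    xs1 = max(p[2] for p in placed)
    ys1 = max(p[3] for p in placed)
    for e in entries:
        e.x -= xs0
        e.y -= ys0
    return xs1 - xs0, ys1 - ys0


def make_entries(
    results: Sequence[AssociationResult],
    frequencies: Dict[str, float],
    max_items: Optional[int] = None,
) -> List[CloudEntry]:
    """Turn significant associations into cloud entries.

    Size weight is |beta| rescaled to (0,1] by the largest |beta| shown;
    color bins are frequency quartiles over the rendered features.
    """
    if not results:
        raise ValueError(
            "no features to render; relax the significance threshold or alpha"
        )
    if any(not r.significant for r in results):
        raise ValueError("only significant features may be rendered")
    ranked = sorted(results, key=lambda r: (-abs(r.beta_std), r.feature_id))
    if max_items is not None:
        ranked = ranked[:max_items]
    top = max(abs(r.beta_std) for r in ranked)
    if top == 0:
        raise ValueError("all coefficients are zero; nothing to scale")
    freqs = np.asarray([frequencies.get(r.feature_id, 0.0) for r in ranked])
    qs = np.quantile(freqs, [0.25, 0.5, 0.75]) if len(freqs) > 1 else freqs[:0]
    entries = []
    for r, f in zip(ranked, freqs):
        color_bin = int(np.searchsorted(qs, f, side="right")) if len(qs) else 3
        entries.append(
            CloudEntry(
                text=r.feature_id,
                size_weight=abs(r.beta_std) / top,
                color_bin=min(color_bin, 3),
                polarity=1 if r.beta_std >= 0 else -1,
            )
        )
    return entries


def _svg_text(e: CloudEntry, dx: float = 0.0, dy: float = 0.0) -> str:
    color = _COLOR_RAMP[e.color_bin]
    return (
        f'<text x="{e.x + dx:.2f}" y="{e.y + dy:.2f}" '
        f'font-size="{e.font_size:.2f}" fill="{color}" '
        f'font-family="sans-serif" text-anchor="middle" '
        f'dominant-baseline="middle">{_escape(e.text)}</text>'
    )


def _escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _write_svg(path, width, height, body: List[str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            '<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{width:.0f}" height="{height:.0f}" '
            f'viewBox="0 0 {width:.2f} {height:.2f}">\n'
        )
        for line in body:
            fh.write(line + "\n")
        fh.write("</svg>\n")


def _write_png(path, entries_with_offsets, width, height) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(width, 1) / 72, max(height, 1) / 72))
    ax.set_xlim(0, max(width, 1))
    ax.set_ylim(max(height, 1), 0)  # svg-style y-down
    ax.axis("off")
    for e, dx, dy in entries_with_offsets:
        ax.text(
            e.x + dx, e.y + dy, e.text, fontsize=e.font_size * 0.75,
            color=_COLOR_RAMP[e.color_bin], ha="center", va="center",
        )
    fig.savefig(path, dpi=72)
    plt.close(fig)


def render_cloud(
    results: Sequence[AssociationResult],
    frequencies: Dict[str, float],
    out_path: str,
    fmt: str = "svg",
    max_items: Optional[int] = 50,
    seed: int = 0,
    min_font: float = 11.0,
    max_font: float = 44.0,
) -> List[CloudEntry]:
    """Render a correlation-scaled cloud to SVG or PNG (+ JSON sidecar).

    Font size is affine in |beta| between ``min_font`` and ``max_font``;
    color comes from a dark-to-light ramp over frequency quartiles.  The same
    seed yields a byte-identical SVG.
    """
    entries = make_entries(results, frequencies, max_items)
    width, height = _spiral_layout(entries, seed, min_font, max_font)
    if fmt == "svg":
        _write_svg(out_path, width, height, [_svg_text(e) for e in entries])
    elif fmt == "png":
        _write_png(out_path, [(e, 0.0, 0.0) for e in entries], width, height)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = [
        {
            "feature": e.text, "size_weight": e.size_weight,
            "color_bin": e.color_bin, "polarity": e.polarity,
            "font_size": e.font_size, "x": e.x, "y": e.y,
        }
        for e in entries
    ]
    with open(str(out_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return entries


def render_topic_panel(
    word_results: Sequence[AssociationResult],
    frequencies: Dict[str, float],
    topic_results: Sequence[AssociationResult],
    topic_top_words: Dict[str, Sequence[str]],
    topic_word_weights: Dict[str, Dict[str, float]],
    out_path: str,
    fmt: str = "svg",
    seed: int = 0,
) -> None:
    """Central words/phrases cloud with up to 6 topic clouds on the perimeter.

    Topics are taken in |beta| order (at most six).  Within a topic cloud
    word size is proportional to p(word|topic); topic word order matches the
    model's top-word ranking.
    """
    import warnings as _w

    central = make_entries(word_results, frequencies)
    cw, ch = _spiral_layout(central, seed, 11.0, 40.0)
    ranked_topics = sorted(
        topic_results, key=lambda r: (-abs(r.beta_std), r.feature_id)
    )[:6]
    if not ranked_topics:
        _w.warn("no topics retained; rendering central cloud only")
    panels = []
    for ti, tres in enumerate(ranked_topics):
        words = list(topic_top_words[tres.feature_id])
        weights = topic_word_weights[tres.feature_id]
        top = max(weights[w] for w in words)
        entries = [
            CloudEntry(
                text=w, size_weight=weights[w] / top, color_bin=3, polarity=1
            )
            for w in words
        ]
        pw, ph = _spiral_layout(entries, seed + 1 + ti, 8.0, 20.0)
        panels.append((tres, entries, pw, ph))

    pad = 30.0
    side_w = max([p[2] for p in panels], default=0.0)
    total_w = cw + 2 * (side_w + pad)
    total_h = max(ch, sum(p[3] for p in panels[0::2]) if panels else 0.0,
                  sum(p[3] for p in panels[1::2]) if panels else 0.0) + pad
    body = []
    for e in central:
        e.x += side_w + pad
        e.y += pad / 2
        body.append(_svg_text(e))
    offsets_left, offsets_right = pad / 2, pad / 2
    placed_entries = [(e, 0.0, 0.0) for e in central]
    for i, (tres, entries, pw, ph) in enumerate(panels):
        if i % 2 == 0:
            dx, dy = 0.0, offsets_left
            offsets_left += ph + pad / 2
        else:
            dx, dy = side_w + pad + cw + pad, offsets_right
            offsets_right += ph + pad / 2
        for e in entries:
            body.append(_svg_text(e, dx, dy))
            placed_entries.append((e, dx, dy))
    if fmt == "svg":
        _write_svg(out_path, total_w, total_h, body)
    elif fmt == "png":
        _write_png(out_path, placed_entries, total_w, total_h)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "central": [e.text for e in central],
        "topics": [t[0].feature_id for t in panels],
    }
    with open(str(out_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# LOESS trend
# ---------------------------------------------------------------------------

def loess_trend(
    feature_values: np.ndarray,
    outcome_values: np.ndarray,
    covariate_values: Optional[np.ndarray] = None,
    grid: Optional[np.ndarray] = None,
    span: float = 0.75,
    n_grid: int = 100,
) -> TrendCurve:
    """First-order LOESS of standardized feature vs a continuous outcome.

    Feature values are z-scored; at each grid point a degree-1 weighted
    least-squares fit on [outcome, covariate] with tricube weights over
    outcome-distance is evaluated, holding the covariate at its sample mean
    (the "neutral" value, e.g. neutral gender).  The grid must lie inside
    the observed outcome range (no extrapolation).
    """
    y = np.asarray(feature_values, dtype=float)
    x = np.asarray(outcome_values, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 observations")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    sd = y.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance feature")
    y = (y - y.mean()) / sd
    if covariate_values is None:
        G = np.empty((len(x), 0))
        g_neutral = np.empty(0)
    else:
        G = np.asarray(covariate_values, dtype=float).reshape(len(x), -1)
        g_neutral = G.mean(axis=0)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid.min() < x.min() or grid.max() > x.max():
        raise ValueError("grid extends beyond the observed outcome range")
    k = max(int(math.ceil(span * len(x))), G.shape[1] + 2)
    fitted = np.empty(len(grid))
    for gi, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = max(d.max(), 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        w[d > h] = 0.0
        D = np.column_stack([np.ones(len(x)), x - x0, G - g_neutral])
        WD = D * w[:, None]
        coef, *_ = np.linalg.lstsq(WD.T @ D, WD.T @ y, rcond=None)
        fitted[gi] = coef[0]
    return TrendCurve(grid=grid, fitted=fitted, span=span,
                      covariate_value=float(g_neutral[0]) if len(g_neutral) else 0.0)


def plot_trend(curve: TrendCurve, out_path, label: str = "feature") -> None:
    """Simple matplotlib rendering of a trend curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(curve.grid, curve.fitted, lw=2)
    ax.set_xlabel("outcome")
    ax.set_ylabel("standardized frequency")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
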