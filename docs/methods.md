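# Methods

This note documents the models, defaults and design choices behind
`openvocab`, and what the synthetic benchmarks do and do not establish.

## Tokenization

The tokenizer is a single regex scan with priority order URL → emoticon →
@-mention → #hashtag → word → single punctuation character. The emoticon
battery covers western faces (`:-)`, `;)`, `:D`, `:/`, mirrored `(-:`),
hearts (`<3`), and eastern faces (`^_^`, `T_T`, `o_O`); a supplement file
(one regex per line) can extend it. Alphabetic tokens are lowercased so
casing variants pool into one feature; emoticons, URLs and punctuation are
left as-is. Elongations ("soooo") are deliberately not normalized and there
is no stemming or spell correction: the unit of analysis is the surface
form. One ambiguity is resolved by a lookahead: the cat-face `:3` is only an
emoticon when not followed by a digit, so clock times ("8:30") split into
digits and a colon rather than into an emoticon.

The tokenizer is a fixed point on its own output (re-tokenizing the
space-joined token list reproduces it), which the property tests exercise on
arbitrary ASCII input.

## Word and phrase features

All contiguous 1–3-grams are extracted within messages; phrases never span a
message boundary. Phrase retention uses PMI with per-order corpus
probabilities, `p(g) = count(g) / total n-grams of that length`, and a
threshold linear in phrase length, `pmi > coef · n` with `coef = 2` in
natural-log units. The threshold scale and log base are configuration
(`pmi_threshold_coef`): `2n` kills independent juxtapositions (PMI ≈ 0)
while passing deterministic collocations (a bigram with
`p(xy) = p(x) = p(y) = 0.01` has PMI = ln 100 ≈ 4.6 > 4).

Two consequences of PMI worth knowing:

- *Rare-pair artifacts*: a pair of rare words co-occurring once can have
  enormous PMI. These candidates are removed by the usage filter (a feature
  must be used by ≥ `ceil(0.01 · n_authors)` authors), which the
  implementation applies before materializing the dense count grid — on a
  2M-token corpus the PMI filter alone passes hundreds of thousands of rare
  phrases of which only a few hundred survive usage filtering.
- A deterministic collocation raises the PMI of every longer n-gram
  containing it (e.g. `a_best_friend` when `best friend` always co-occurs);
  such super-phrases legitimately pass the filter when common enough.

Counts are normalized by the author's **total unigram count** (phrases
included — the denominator is the author's total word use, not the per-order
n-gram count), transformed with Anscombe's `2√(p + 3/8)`, so cell values lie
in `[2√(3/8), 2√(11/8)]` and an author who never uses a feature contributes
`anscombe(0)`, not a hole. `NgramVectorizer` has a fit/transform split:
vocabulary, corpus probabilities, the retained-phrase set and the usage
threshold are learned on one author set (e.g. training authors) and applied
frozen to any other; out-of-vocabulary tokens in new text count toward the
normalizing denominator but can never create a feature.

## Topics

LDA is fitted by collapsed Gibbs sampling with **messages as documents**
(short messages mix few topics, hence a small document-topic concentration;
default `alpha = 0.3`, `beta = 0.01`, `n_iter = 1000`, `K = 50` for
desk-scale corpora — all configurable, and thousands of topics are feasible
only with correspondingly large corpora). The inner loop is JIT-compiled
with numba; the sampler seeds its own RNG, so a fitted model is a
deterministic function of (documents, K, alpha, beta, n_iter, seed).
`phi = (c_kw + β)/(c_k + Vβ)` is read off the final sample — no averaging
across samples, no hyperparameter optimization. An externally estimated
topic-word table (CSV `word,topic,weight`, e.g. exported from Mallet) can be
imported in place of the in-package sampler.

Author topic usage is not per-document inference: it is
`p(t|author) = Σ_w p(t|w) p(w|author)` with `p(t|w)` from assignment counts
and `p(w|author)` renormalized over the model vocabulary. This makes usage
invariant to duplicating an author's messages and keeps the usage vector a
proper distribution. No stopword list is applied by default (open-vocabulary
principle); one can be supplied.

## Mass-univariate association

Each feature gets its own OLS of the z-scored outcome on [z-scored feature,
z-scored covariates, intercept]; the feature coefficient is the standardized
β reported. Covariates are standardized too — this does not change the
feature coefficient's test, and makes reported covariate effects comparable.
Authors missing the outcome or a covariate are dropped per outcome (pairwise
deletion). p-values are two-tailed from the t distribution with
`n − n_covariates − 2` degrees of freedom, which matters at fixture sizes.
`run_dla` computes all features at once through the Frisch–Waugh–Lovell
identity (residualize outcome and features on the covariates once); the
single-feature route through statsmodels is kept as an independent path and
the tests require the two to agree to 1e-10. Zero-variance features are
skipped with a log entry and reported with p = 1, never silently dropped.

Corrections: Bonferroni (`family_alpha / m`, default family α = 0.001,
two-tailed) and Benjamini–Hochberg step-up. The BH implementation is the
six-line step-up definition; tests verify it against both a brute-force
evaluation of the definition (m ≤ 10) and statsmodels' `fdr_bh`.

`power_analysis` redraws author subsamples without replacement, **recomputes
the usage-filtered feature set on each subsample**, reruns the analysis and
averages the significant-feature count — so the feature family shrinks with
the subsample exactly as it would in a smaller study.

## Visualization

Phrase pruning scans results by descending |β|: single words always stay; a
phrase overlapping an already-kept feature stays only if each of its extra
words is strictly rarer than the least frequent shared word. The published
rule is stated through one worked example (day / beautiful day / the day);
the "least frequent shared word, strict inequality, ties drop" reading is
our generalization, chosen to be conservative (sparser clouds). Topic
pruning drops a topic when its top-15 overlap with any kept topic exceeds
25% — i.e. 4 shared words trigger the drop, 3 do not.

Cloud layout is a seeded Archimedean spiral with rectangle collision over
fixed approximate glyph metrics, written by an in-package SVG emitter with
fixed float formatting: the same seed yields a byte-identical file.
Aesthetics are explicitly not a contract; determinism is. Font size is
affine in |β| (defaults 11–44 pt); color is a 4-bin dark-to-light ramp over
frequency quartiles of the rendered features. Panels place up to the 6
strongest topics around the central word/phrase cloud, with topic-word size
proportional to `p(w|topic)`. Every figure gets a JSON sidecar listing each
rendered feature with β, frequency bin and position.

LOESS trends are first-order (local linear) with tricube weights over the
span-nearest neighbors (default span 0.75, 100-point grid over the observed
range, no extrapolation). The covariate (e.g. gender) enters the local
design and is held at its sample mean at evaluation — the "neutral" value.
A hand-rolled weighted least squares is used because the covariate-adjusted
variant is the contract; it reproduces a global line to 1e-6 on noiseless
linear data.

## Predictive evaluation

One seeded 75/25 author split is shared by every feature set. Feature
builders are fitted on training authors only (PMI probabilities, usage
thresholds, topic model, PCA, scaling); unions are column-concatenations
with name deduplication, formed before PCA. PCA reduces to
`min(n_train/2, n_features, n_train − 1)` centered (not whitened)
components. The regularization grid is 7 log-spaced values (1e-3…1e3, the
source protocol names none); selection trains on 90% of the training
authors and scores on the held-out 10%, then refits on all training
authors. Out-of-sample R is clipped at zero before the square root
(negative out-of-sample R² reports as R = 0). The improvement test is a
paired bootstrap over test authors (default 2000 resamples; the metric is
recomputed on each resample for both models and the one-sided
`P(candidate ≤ baseline)` reported with the +1/(B+1) correction) — the
source protocol states only "significant improvement", so the test is our
choice.

## Synthetic corpora

`generate` emulates the statistical shape of a large status-update corpus:
per author, Poisson(206) messages of Poisson(20) words (≈ 4,100 words per
author, matching the regime of roughly 206 statuses × 20 words); a
2,000-type background vocabulary with Zipf exponent 1.1 (heavy-tailed but
desk-scale); fixed collocations emitted as intact word sequences; emoticon
tokens; outcomes gender ~ Bernoulli(0.5) coded 0/1, age ~ 13 + lognormal
matched to mean 23.43 / SD 8.96, five standard-normal traits. Planted
effects multiply a feature's sampling weight by `exp(effect · z_outcome)` —
log-rate shifts keep frequencies positive and yield small standardized βs
like real text. The vocabulary is a fixed common-word core plus
deterministic pronounceable pseudo-words, so no accidental semantics leak
into tests. Ground truth (planted effects, collocations, generator
parameters) is written alongside the corpus; recovery tests score against
that file only.

`generate_topic_corpus` draws, per author, a softmax topic mixture
(optionally shifted by a trait for one planted topic), per message a
Dirichlet perturbation of it, and per word a topic then a word from that
topic's distribution — by default disjoint per-topic vocabulary blocks, or
a caller-supplied known `phi`.

What the generator does **not** emulate: real lexical semantics, burstiness
beyond Poisson mixing, author-specific style, message-length/topic
correlation, non-stationary language. Passing tests therefore establish the
statistical machinery (calibration, recovery, ordering of feature sets
under planted signal), not performance on real social-media text.

## Benchmark sizes and expected behavior

The heavy checks run at 500 authors (~2M tokens, ~2,300 surviving features)
for null calibration and planted-word recovery (rate ×3 across ≈5 SD of the
outcome range, i.e. effect `ln(3)/5` per SD), 200 authors / K = 5 for
planted-topic recovery, and 300 authors for the predictive benchmark, where
30 gender-marker words are planted outside a 6-category demo lexicon
(alternating log-rate effects ±0.5 per SD). Under those conditions
open-vocabulary features classify held-out authors near-perfectly while the
lexicon — which by construction carries no signal words — stays near chance,
reproducing the qualitative ordering that motivates open-vocabulary
analysis, and adding lexicon features to open features yields no significant
further gain. `scripts/acceptance.py` re-measures all of this from scratch
at a given seed; its replicate counts (10 per simulation) and the test
suite's (20) are the package's chosen problem sizes.

## Known limitations

- The Gibbs sampler uses a single final sample; φ estimates are noisier
  than averaged-sample or variational estimates at small `n_iter`.
- PMI probabilities are per-order maximum-likelihood; no smoothing, so an
  unseen phrase has PMI −∞ by construction rather than a finite estimate.
- `compare_feature_sets` rebuilds features per call; comparing many unions
  re-fits nothing but still re-transforms matrices.
- Word-cloud glyph metrics are approximate (0.6 em per character); layouts
  are collision-free in that metric, not in the renderer's exact font
  metrics.
- The author-inclusion filter cannot enforce a primary-language criterion;
  no such metadata exists in the input formats.
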