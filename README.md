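# openvocab

Open-vocabulary **differential language analysis (DLA)** for linking language
use in short social-media messages with person-level attributes (gender, age,
personality traits — any numeric outcome attached to an author).

Instead of restricting analysis to a priori word categories (the
closed-vocabulary approach of LIWC-style lexica), DLA builds its feature set
from the corpus itself — every word, phrase and data-driven topic — and asks,
for each feature independently, how strongly it distinguishes an outcome once
covariates are controlled for. The package is aimed at computational social
scientists and psychometricians who have (a) a message corpus keyed by
author and (b) an outcomes table per author, and want ranked, corrected,
visualizable language correlates plus an out-of-sample predictive comparison
of feature sets.

## Method

**Features.**

- *Words and phrases*: contiguous n-grams of size 1–3 within a message,
  tokenized by an emoticon-aware tokenizer (`:-)`, `<3`, `^_^` survive as
  tokens). Phrases are kept only when their pointwise mutual information

      pmi(phrase) = log [ p(phrase) / ∏ᵢ p(wordᵢ) ]

  exceeds a length-scaled threshold (default `2·n` in natural-log units),
  separating true collocations from accidental juxtapositions. Counts are
  normalized by each author's total word use and variance-stabilized with
  the Anscombe transform `x ↦ 2√(x + 3/8)`; features used by fewer than 1%
  of authors are dropped.
- *Topics*: LDA fitted by collapsed Gibbs sampling with messages as
  documents. An author's topic usage is
  `p(topic | author) = Σ_w p(topic | w) · p(w | author)`.
- *Categories* (closed-vocabulary baseline): the fraction of an author's
  words matching a category's patterns (literal tokens or `stem*`
  wildcards), in LIWC `.dic` or plain CSV format.

**Association.** For each (feature, outcome) pair, OLS of the z-scored
outcome on the z-scored feature plus z-scored covariates; the feature's
standardized coefficient β is its correlation strength (β equals Pearson's r
when there are no covariates). Two-tailed p-values come from the t
distribution; the family of features for an outcome is corrected by
Bonferroni (default family α = 0.001, i.e. a per-test threshold of
`0.001 / m`) or Benjamini–Hochberg step-up FDR.

**Visualization.** Word clouds scale font size by |β| and color by corpus
frequency, after redundancy pruning ("beautiful day" is kept next to "day"
because *beautiful* is rarer than *day*; "the day" is dropped), and topic
clouds are deduplicated when more than 25% of their top-15 words repeat a
higher-ranked topic. Continuous outcomes get first-order LOESS trends of
standardized frequency, covariate-adjusted and evaluated at a neutral
covariate value.

**Prediction.** 75/25 author split, PCA to half the number of training
users, linear SVM (binary outcomes) or ridge regression (continuous), with
the regularization value chosen on a 10% validation slice of the training
set. Metrics: accuracy, or R = √(max(0, 1 − SSE/SST)) on test authors;
feature-set improvements are tested with a paired bootstrap over test
authors.

A synthetic-corpus generator (`openvocab.synth`) provides corpora with the
statistical shape of a large status-update dataset — hundreds of short
messages per author, Zipfian vocabulary, fixed collocations, emoticons,
skewed age — and *planted* language–outcome effects recorded in a
ground-truth file, so every statistical claim in the test suite is checked
against known structure.

## Worked example

```python
from openvocab.synth import SyntheticSpec, PlantedEffect, generate
from openvocab.features import NgramVectorizer
from openvocab.stats import run_dla, CorrectionSpec

spec = SyntheticSpec(
    n_authors=200, seed=7,
    planted_effects=[
        PlantedEffect("time", "extraversion", 0.30),
        PlantedEffect("happy birthday", "extraversion", 0.25),
    ],
)
corpus_data = generate(spec)
corpus = corpus_data.author_corpus()
matrix = NgramVectorizer().fit_transform(corpus)
print(f"{len(matrix.authors)} authors x {len(matrix.features)} features")
results = run_dla(matrix, corpus_data.outcomes, "extraversion",
                  covariates=["gender", "age"],
                  correction=CorrectionSpec("bonferroni", 0.001))
for r in results[:4]:
    print(f"{r.feature_id:>16s}  beta={r.beta_std:+.3f}  p={r.p_value:.2e}")
```

prints

```
200 authors x 2904 features
            time  beta=+0.777  p=1.88e-42
        birthday  beta=+0.567  p=1.27e-18
  happy_birthday  beta=+0.567  p=1.27e-18
           happy  beta=+0.360  p=1.58e-07
```

The planted word `time` (usage rate increasing with extraversion) tops the
ranking; the planted collocation surfaces both as the phrase
`happy_birthday` — retained by the PMI filter — and through its component
words; all four pass the Bonferroni-corrected threshold, and nothing else
does.

The same pipeline is available as a CLI:

```bash
openvocab synth   --out-dir demo --n-authors 200 --seed 7 \
                  --planted time:extraversion:0.3
openvocab extract --messages demo/messages.csv --outcomes demo/outcomes.csv \
                  --out-dir demo/features
openvocab dla     --features demo/features/features.csv \
                  --outcomes demo/outcomes.csv --outcome extraversion \
                  --covariates gender,age --out-dir demo/dla
openvocab cloud   --associations demo/dla/associations.csv \
                  --vocabulary demo/features/vocabulary.tsv \
                  --out demo/cloud.svg
```

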