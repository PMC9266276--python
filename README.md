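# sweetreview

Mining sweetness-level mentions from food-product review corpora: phrase
tagging with negation and exclusion handling, classification of oversweet
mentions that actually refer to the purchased product, sweetener-enrichment
and rating statistics, and a synthetic corpus generator with planted ground
truth so the whole pipeline is testable offline.

## What it does

- **corpus_io** — read/write review and product tables (CSV/TSV),
  deduplicate reviews, normalize ingredient strings and detect sweeteners
  against a packaged catalog (canonical names, synonyms, caloric class).
- **lexicon** — expand base sweetness phrases with negation prefixes
  (levels flipped through an editable table), misspellings and exclusion
  suffixes ("sweet tooth", "sweet leaf") into a validated phrase lexicon.
- **sweetmatch** — tokenize review text, extract one-word environments
  around sweet-family words, resolve each mention
  (excluded > longest phrase > sweet-only) and tally reviews per level.
- **word_categories** — percentage of reviews mentioning each word category
  (taste, texture, price, customer service, health, olfaction, chemesthesis).
- **classify** — bag-of-words gradient-boosted classifier separating real
  oversweet complaints from phrase-only mentions (e.g. comparisons to other
  brands), with grid-searched hyperparameters and F1-scored k-fold CV.
- **stats** — per-sweetener and per-caloric-class oversweet enrichment
  (two-sided proportion test matching R's `prop.test`, Bonferroni), product
  rating comparisons (one-sided rank-sum, Benjamini–Hochberg), and
  per-customer dispersion of oversweet reviews.
- **synthetic_data** — simulated corpora with planted oversweet prevalence,
  per-sweetener effects, rating penalty and decoy reviews, plus row-level
  ground truth for recovery tests.

## CLI

The `sweet` command exposes the pipeline stages:

```
sweet simulate --seed 1 --out corpus/           # synthetic corpus + ground truth
sweet lexicon build --out lexicon.tsv           # expanded phrase lexicon + summary
sweet tally --reviews corpus/reviews.csv --out tally.tsv --audit mentions.tsv
sweet categories --reviews corpus/reviews.csv --out categories.tsv
sweet train --reviews corpus/reviews.csv --labels labels.tsv --out model/
sweet predict --reviews corpus/reviews.csv --model model/ --out predicted.tsv
sweet stats --reviews corpus/reviews.csv --products corpus/products.csv \
            --labels labels.tsv --out stats/
sweet run --seed 1 --out run/                   # full pipeline + run manifest
sweet run --show-config                         # print default config JSON
```

`sweet run` executes simulate → dedup → tally → train → predict → stats and
writes a `manifest.json` recording version, seed, thresholds, input digests,
lexicon version and per-stage timing.

## Data files

Packaged defaults live in `src/sweetreview/data/`: base sweetness phrases,
filler words, the sweetener catalog, word-category lists and review-text
templates. All are plain TSV/text and can be swapped out via the relevant
loader arguments or CLI flags.
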