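# Methods

This note documents the modeling choices behind `medtopic`: what each
stage assumes, which parameters matter, and where the design was genuinely
open.

## Preprocessing and noise filtering

Messages are lowercased and split on non-alphanumerics, keeping intra-word
hyphens and apostrophes ("x-ray", "paget's"). Content tokens drop stop
words (a packaged ~150-word English list, overridable) and tokens shorter
than `min_token_len` (default 2), then apply the classic Porter suffix
stripper — implemented in-package (`_porter.py`) from the original
five-step description and tested against its published example pairs.
Only purely alphabetic tokens are stemmed; hyphenated or digit-bearing
tokens pass through unchanged.

"Emotional" messages ("Thank you for your answer") carry no medical
content and hurt topic clustering. Since manual screening is not
reproducible, filtering is operationalized as: keep a message iff it has
at least `noise_min_content_tokens` (default 3) content tokens **and** at
least one lexicon term match. The filter is idempotent.

## Lexicon matching

A typed term lexicon (term → set of semantic-type codes, 20-type closed
set) stands in for full biomedical concept mapping. Matching is greedy
left-to-right longest-match over stemmed content tokens, emitting
non-overlapping spans. This deliberately omits variant generation and
word-sense disambiguation: downstream features only use term counts per
semantic type, for which exact dictionary matching is an adequate,
testable surrogate. A term carrying several types contributes one count
to each of its type columns. The packaged toy lexicon (~140 oncology and
diabetes forum terms) exists for demonstrations and tests; real analyses
should supply their own lexicon TSV.

One consequence of matching over *content* tokens: a lexicon term that
contains a stop word ("shortness **of** breath") can only match if the
stoplist used for messages is also applied to the lexicon
(`load_lexicon(..., stoplist=...)`); by default lexicon terms are stemmed
but not stop-filtered.

## Features

Five column blocks: unigram/bigram/trigram counts over the contiguous
content-token sequence (n-grams do not bridge removed stop words), counts
per matched medical term, and counts per semantic type. N-gram columns
require `min_df >= 3` distinct messages (controls n-gram explosion; there
is no canonical value for forum text). `vectorize` produces raw counts by
default; the pipeline enables per-message length normalization (below).

## PCA

Computed by SVD of the centered dense matrix; no unit-variance scaling
(all blocks share count units); deterministic sign convention (largest
loading positive). Two retention rules:

- `coverage`: smallest m reaching a cumulative explained-variance target
  (default 0.95) — the conventional rule, kept as `fit_pca`'s default;
- `elbow`: the m maximizing the successive eigenvalue drop ratio within
  the first 50 components — the scree elbow.

The pipeline defaults to `elbow`. On bag-of-words counts the variance is
diffuse: 0.95 coverage retains hundreds of near-noise directions and is
no reduction at all, while the between-topic subspace shows up as a sharp
3–5× eigenvalue drop after the leading components. Measured on synthetic
corpora, clustering in the elbow subspace is dramatically more accurate
than in the full coverage space.

## Length normalization

The pipeline divides each message's counts by its content length before
PCA. Message length is the dominant nuisance variable in forum text —
every count column correlates with it — and a Gaussian mixture on
unnormalized counts prefers splitting messages by length over splitting
them by topic (observed directly: Rand ≈ 0.5 against planted topics
without normalization vs ≈ 0.97 with it, at the same K).

## EM clustering

Diagonal-Gaussian mixture, log-space densities, responsibilities
normalized per row. Initialization seeds the K means from data points
k-means++-style with the global per-dimension std and uniform weights;
`n_init = 5` restarts for final fits keep the best final likelihood.
Convergence: the fit stops when the *mean per-row* log-likelihood gains
less than `tol = 1e-6` — the per-instance scaling keeps the threshold
meaningful across corpus sizes. A component losing all responsibility is
re-seeded from a random row (logged).

Two regularizations matter on count-derived features:

- **Variance floor.** Component stds are floored; `EMConfig.min_std`
  (default 1e-6) is the absolute floor, and the pipeline raises it to
  `variance_floor_frac = 0.2` of the reduced matrix's global std.
  Count-derived features take discrete, lattice-like values; without a
  meaningful floor, components specialize on lattice clumps (stds of
  1e-3 and below) and the mixture stops describing topics. Proportional
  variance flooring is standard mixture-model practice.
- **Monotone termination.** The floor is a projection, not a constrained
  M-step, so when it binds an iteration can slightly lower the
  likelihood; the fit then terminates at the previous (better)
  parameters. The recorded `loglik_trace` is therefore non-decreasing by
  construction, matching the theory it is meant to exhibit.

## Choosing the number of clusters

`select_k_cv` splits rows into `cv_folds = 10` seeded folds and, for
K = 1, 2, …, fits on each training split (`cv_n_init = 2` restarts — a
runtime/robustness compromise; classical implementations use one) and
records the mean held-out per-row log-likelihood. K grows while that
score keeps improving *appreciably*: a step must be positive and at least
`min_gain_frac = 0.2` of the largest step seen so far. With
`min_gain_frac = 0` this is the strict any-improvement rule.

The relative threshold is the one place where a textbook rule had to be
refined. On discrete count features every extra component genuinely
improves held-out likelihood a little — it carves count-lattice and skew
structure inside clusters — at every dimensionality we measured, so the
strict rule never stops and always returns `k_max`. On data that actually
matches the model (Gaussian blobs) the two rules agree, because gains
past the true K are at noise level. The 0.2 fraction reads "stopped
increasing" at the resolution of the curve's own scale: measured
improvement steps drop by 2.5–6× at the true K and stay low after.

## Key phrases and labels

Candidates are all content n-grams (n ≤ 3) plus matched lexicon terms;
frequencies are token occurrence counts (document-frequency mode
available). The score `f(w, C_i) · ln(N / n_w)` uses the natural log, and
`n_w` counts clusters with frequency ≥ the evaluated one, so `n_w ≥ 1`
and an evenly-spread term scores exactly 0. One caveat: `f` is raw, so in
the largest cluster a ubiquitous background word whose count merely
*leads* the other clusters can outrank genuinely characteristic terms —
visible in synthetic runs and inherent to the formula.

Cluster labels come from the summed semantic-type counts of member
messages: the top type maps sosy → Symptom, dsyn/patf → Complication,
diap/lbpr → Examination, topp → Procedure, phsu → Drug; anything else
(or no counts) → Other. Clusters sharing a label are reported as
mergeable.

## Evaluation

Pair counts are computed by contingency-table algebra (binomials of the
table, row and column margins) and verified against O(n²) enumeration in
tests. Degenerate conventions: Jaccard and FM are 0 when their
denominators vanish; kappa with chance agreement 1 is 1 for perfect
agreement, else 0. Kappa is unweighted (nominal categories).

## Synthetic corpora

The generator emulates the statistical structure the pipeline assumes: K
topics drawn uniformly; per message, `max(1, Poisson(topic_term_rate))`
topic-term draws taken from the own topic's term set with probability
`separation` (else a random other topic's), plus `Poisson(background_rate)`
background tokens from a Zipf-weighted vocabulary; a `noise_rate` fraction
of messages instead draw from a pool of emotional phrases and contain no
lexicon term. Topic term sets are disjoint and typed per a profile cycling
sosy/dsyn/diap/topp/phsu, so ground truth, expected labels and lexicon
come out of the same configuration. Defaults — 5 topics, 2000 messages,
20 terms/topic, rates 6 and 12, 300 background words, separation 0.9,
noise 0.1 — describe a desk-scale board where topical vocabulary is about
a third of a message's tokens.

What the generator does *not* emulate: grammar and word order (emission
is bag-of-words, so the bigram/trigram blocks carry little signal beyond
multiword terms), thread structure, author styles, temporal trends, and
lexicon noise (every planted term is in the lexicon; there are no
out-of-lexicon medical mentions or ambiguous terms). Passing end-to-end
tests therefore demonstrates that the machinery recovers planted
structure under realistic count noise — not that it would resolve the
far messier topic structure of real forum text.

## Problem sizes in tests and experiments

The validation experiments use 50 random mixture fits for monotonicity,
200 random labelings (n ≤ 50) for the pair-counting oracle, 10 seeds of
180-point Gaussian blob data for cluster-count recovery, 10 synthetic
corpora of 2000 messages (K cycling 3/4/5) for end-to-end recovery, and
10 corpora of 1000 messages for the F1 vs F1+F2 comparison — sizes at
which each effect is comfortably measurable on a single CPU. End-to-end
recovery is stochastic: across base seeds the success rate ranges about
0.7–0.9 with mean Rand ≈ 0.95.

## Known limitations

- The key-phrase score favors the largest cluster for ubiquitous terms
  (see above).
- Greedy longest-match cannot represent overlapping or nested concepts.
- Diagonal covariance cannot model correlated within-topic variation;
  PCA decorrelation mitigates but does not remove this.
- The cross-validated K is sensitive to `min_gain_frac` on data whose
  within-cluster shape is strongly non-Gaussian; the default favors
  parsimony.
- Timestamps are carried but never modeled.
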