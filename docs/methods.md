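# Methods

This note records the models, parameter choices, and numerical decisions
behind `counselhelp`, and what the synthetic experiments do and do not
establish about real counseling Q&A data.

## The outcome and its generative stand-in

The outcome is the count of helpful votes a counselor's response
receives.  Platform data of this kind shows votes from 1 upward with a
mean near 4.36, questions averaging about 185 tokens and responses about
388.  The synthetic generator encodes exactly those conditions as its
defaults: document lengths are Poisson with means 185/388, and votes are

    votes = 1 + Poisson(exp(eta)),
    eta   = intercept + sum_f coef_f * (x_f - center_f)

so the support starts at 1 by construction.  The default intercept is
log 3.362, giving mean votes 1 + 3.362 = 4.362 when all effects are
zero.  A negative-binomial noise option (`dispersion`, NB2 size) exists
for overdispersion studies.  The linear predictor may reference latent
quantities by name: per-category emission rates of either speaker (on
the percent scale), document lengths (per 100 tokens), and the true
synchrony scores.  Centers are fixed at the latent expectations under
the default rate ranges (measured once on a large zero-effect reference
run) so the intercept keeps its meaning when effects are planted.

Documents are multinomial token streams over a synthetic pseudo-word
vocabulary: every leaf category (function words, emotion, cognition,
topics, filler, ...) has a per-document emission probability drawn
uniformly from a configured range.  Because the bundled dictionary
captures each category's word pool exactly (some categories via stem
patterns, to exercise that matcher path), the computed category
proportions are unbiased estimates of the latent rates, converging as
documents lengthen — the lever behind every parameter-recovery test.
Sentences are closed by periods at geometric lengths (mean 14 words), 
with occasional colons/quotes/parentheses so the stylistic counters see
variation.  Rate-range validation requires the worst-case rate sum to
stay below 0.98 so filler mass always remains.

Dyadic synchrony is controllable: the response's function-word and
emotion-leaf rates are convex mixtures of the question's rates and fresh
draws (`lsm_strength` = 0.7, `emotion_corr` = 0.6 by default), and each
question topic survives into the response with probability
`topic_overlap` = 0.7 on top of a 0.1 background activation.  Topic
incidence stored as truth is the *token-backed* incidence (a planted
topic that happens to emit no token is recorded as absent), so truth and
recomputation agree exactly.  Rate-level truth stores expectations, not
realized counts.

## Feature extraction

Category proportions use word tokens as the denominator (punctuation
excluded), LIWC convention; a token may count toward several categories.
An empty document yields zeros plus a flag, never NaN.  A document with
no terminal punctuation counts as one sentence.  `RateFourCharWord` is
the share of tokens at least four symbols long.  Every feature column
carries a (source, type) tag; the source is counselee (question),
counselor (response), or synchrony, and the types follow the standard
LIWC-style groups (affective/biological/cognitive/perceptual processes,
drives, informal language, numbers, personal concerns, personal
pronouns, prepositions, relativity, social processes, stylistic, time
orientations) plus the four synchrony types (LSM, AffectSIM,
SymptomsSIM, FactorsSIM).

## Synchrony scores

The three statistics are symmetric and bounded in [0, 1].  Degenerate
inputs score 0 and are flagged rather than treated as agreement: a
topic-incidence Jaccard with an empty union returns 0 (absence of any
topic signal is not evidence of consistency), and the emotion cosine of
an all-zero vector returns 0 (no expressed emotion, no measurable
similarity).  LSM applies its 0.0001 smoothing constant on the percent
scale exactly as the formula is written, which forces a score of 1 when
neither speaker uses a category.  The nine LSM categories are a named
configurable group; a dictionary lacking one (articles, say) must
declare the absence by passing a shorter group, never silently.

## Topic detection

The embedding is count-based: a positive-PMI co-occurrence matrix
factorized by truncated SVD (50 dimensions, seeded), with `window = 0`
meaning whole-document co-occurrence — the right granularity when
document-level topic association is the signal.  A spectral estimator is
deterministic under a fixed seed, which this pipeline values over
stochastic-gradient training; it has no epochs parameter.  Stop words
(for the synthetic language: function words and filler, the closed-class
glue) are removed before embedding training and only there — removing
them from the counting paths would destroy the LSM substrate.

Seed words (two per topic) are expanded at cosine threshold 0.5
(configurable; in manual-curation settings this threshold is a human
judgement).  The expanded vocabulary is clustered by k-means with k
chosen by silhouette over 2–10 (ties to the smaller k), and the
resulting clusters define topic word lists; incidence is then lexical
matching against those lists, not nearest-centroid assignment.  A config
override can pin k (e.g. at 7) while still reporting the silhouette
trace, since a study may fix the topic count on substantive grounds.

Known limitation: on the default synthetic corpus the silhouette
criterion does not recover the planted 7+7 topics through the full text
path — the expanded lexicon drags in general content words and the
criterion prefers finer splits (the analysis run chooses k = 10).  The
clustering machinery itself recovers planted counts c ∈ {3, 5, 7}
reliably on well-separated embeddings (tested); the gap is the
expansion step's precision at desk-scale corpora, and mirrors why manual
threshold curation is used in practice.

## Model comparison

Five regressors — OLS, ridge (α = 1), lasso (α = 1), linear-kernel SVR
(C = 1, ε = 0.1), random forest (500 trees by default, seeded; the
analysis scripts use 200) — are compared by ten-fold cross-validated
MAE.  The outcome enters untransformed (a `log1p` option exists).  One
seeded shuffled fold partition is shared across every algorithm ×
feature-source cell, so the grid is paired and cell differences are not
fold noise.  The grid carries per-algorithm and per-source means.

## Attribution layer

Shapley attributions are authored in-package (no external explainer):

* **exact-tree** — path-dependent TreeSHAP over sklearn tree arrays,
  numba-compiled.  The coalition value function is the tree-traversal
  conditional expectation with cover weighting.  Inputs are cast through
  float32 before threshold comparisons to replicate sklearn's own
  routing, which matters on discrete-valued features.  Verified against
  an exhaustive-coalition brute-force oracle (identical value function,
  factorial Shapley sum) to < 1e-8 on a suite of small trees; additivity
  (base + row sum = prediction) holds to float accumulation.
* **sampling-kernel** — interventional Shapley against a background
  sample (a seeded subsample of at most 100 analysis rows by default):
  exact coalition enumeration up to 11 features, seeded Shapley-kernel
  weighted least squares beyond, with the efficiency constraint enforced
  so additivity is exact by construction.

Attributions are computed on the full analysis table with the
fitted-on-all-data model (train/test provenance of an attribution matrix
is an open choice; this one is recorded and configurable).  The
explanation forest is depth-limited (depth 8, 200–300 trees in the
scripts): unlimited-depth forests at these sample sizes cost quadratic
path time in TreeSHAP while adding only noise splits.

Grouped decomposition sums positive and negative attributions per group
over all observations; total effect = positive + |negative|; shares are
totals over the grand total and sum to 100 up to rounding.  Merging
groups adds the signed fields exactly.  Feature importance for the
ranking is the total effect, matching the decomposition arithmetic, with
mean |SHAP| emitted alongside as the alternative ordering; ties break on
feature name so the ranking is column-order invariant.

Attribution-profile clustering uses average-linkage hierarchical
clustering on 1 − Pearson correlation between attribution columns, cut
at five clusters; constant columns are excluded with a warning since
their correlation is undefined.

## Incremental selection

Features are added in ranking order and the model re-cross-validated at
each k (shared folds across k); best k is the argmin, ties to the
smaller k.  A capacity note, established empirically in this package's
tests: with a many-tree forest the MAE curve is flat past the
informative features — averaging absorbs the variance that irrelevant
features inject, so the argmin wanders over near-ties.  The planted-
recovery experiment therefore runs its selection curve with OLS, whose
excess risk grows systematically with every irrelevant regressor
(≈ σ²k/n), giving the curve a genuine interior minimum; the forest-based
curve is still produced by the analysis scripts, as in the original
design, and its flatness at desk scale is reported as-is.

## Problem sizes

The analysis scripts and the acceptance script run at 400 pairs,
ten-fold CV, 200-tree forests, selection up to k = 25; the recovery
experiments use n = 1000 with 3 informative and 17 null features over
seeds 1–5; the additivity check runs a 500-pair corpus.  These sizes
give stable statistics for every reported quantity while keeping a full
run in minutes on one CPU.

## What passing tests show — and what they do not

The synthetic corpus has known rates, known synchrony, and a known vote
model, so the tests establish correctness of the measurement and
explanation machinery: formulas compute what they claim, estimates
converge to truth, planted effects are found with the right sign and
rank, and accounting identities hold exactly.  They do not establish
that these features predict real helpfulness votes: synthetic text has
no grammar, no topic-category correlation structure, no selection
effects in who votes, and its vote model is the package's own
construction.  Conclusions about real platforms require real corpora
through the same interfaces (a line-delimited corpus file, a `.dic`
dictionary, seed-word lists).
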