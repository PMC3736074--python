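# Methods

This note records the model, the protocol, the synthetic study
conditions, and the design decisions behind `healthtopics`, in the order
the pipeline runs.

## Preprocessing

Tokens are maximal runs of letters, digits and apostrophes in the
lowercased text; every other character (including hyphens) separates
tokens, so "HER2-positive" tokenizes as `her2`, `positive`. This rule is
frozen because feature counts must be exactly reproducible. Stop words
(a fixed, shipped list of ~150 English function words, user-overridable)
are removed **before** stemming and before n-gram formation, so a bigram
may span a removed stop word; this choice is documented rather than
configurable. Stemming is the classic Porter (1980) five-step algorithm,
implemented here and verified against the published example vocabulary
(note the algorithm is not idempotent on every output, e.g. `agreed →
agre → agr`). Two token views are retained per message: the **raw**
lowercased tokens, used for lexicon matching because lexicon entries are
dictionary forms, and the **stemmed** stop-filtered tokens, used for
n-grams.

## Lexicons

The domain lexicon is a two-column TSV (`term<TAB>code`), filtered to the
20 health-related UMLS semantic-type abbreviations (Aapp … Topp). The
native UMLS release format is deliberately out of scope: UMLS is licensed
and large, so the TSV is the interoperable surface and conversion from a
real UMLS installation is a user-side step. Terms are 1–3-word lowercase
phrases; a term listed under several codes becomes one entry with the
merged code set, making loading order-independent. The shipped
`data/domain_lexicon.tsv` is a ~200-term synthetic fixture written for
tests and demos, not derived from UMLS data.

The sentiment lexicon uses the SentiWordNet-3.0 file layout (POS, ID,
PosScore, NegScore, SynsetTerms as `lemma#rank`). Subjectivity of a lemma
is 1 − objectivity aggregated over senses; the default aggregation is the
unweighted arithmetic mean of per-sense (pos + neg), chosen because it is
symmetric and assumption-free; 1/rank weighting is available as an
option. The selection boundary is strict: a lemma qualifies only when its
subjectivity is **strictly greater than** 0.5 (so exactly 0.5 is
excluded). Part of speech is ignored when pooling senses, since the
pipeline does not POS-tag tokens. `data/sentiwordnet_mini.txt` is again a
synthetic fixture in the real format.

## Features and feature sets

Feature values are binary presence indicators (occurrence counts are an
opt-in variant); the three families are namespaced (`ngram:`, `domain:`,
`sentiment:`) so a string that is both a frequent unigram and a lexicon
term contributes two distinct columns. n-grams run over n = 1..3; longer
sequences are out of scope. The n-gram vocabulary keeps grams whose
**total corpus occurrence count** is ≥ the frequency threshold (default
20); document-frequency counting is an option. Domain matching is greedy
left-to-right longest-match (≤ 3 tokens) with non-overlapping spans, so
"breast cancer" consumes "cancer". Domain and sentiment descriptors are
admitted on any observed occurrence — no frequency threshold — because
lexicon membership already acts as the filter.

FS4 reduces the **n-gram family only** by information gain, keeping
gains strictly greater than 0.0025. Gains are in bits (log base 2, with
base-e as an option); the threshold's base-dependence is noted here
because the convention in this line of work is base 2 but the published
threshold does not state it. Probabilities in the gain formula are
maximum-likelihood count ratios with 0·log 0 = 0; no smoothing is
applied or needed under that convention.

Within cross-validation, the vocabulary and the FS4 gain reduction are
recomputed **on the training fold only** — the leakage-free default — with
a `paper_mode` flag that instead builds them once on the full corpus, for
fidelity with evaluation setups that did not separate feature selection
from the folds.

## Classifiers

* **Bernoulli naive Bayes** (authored here): priors are class-count
  ratios; presence probabilities use add-α smoothing,
  (n_present + α)/(n_class + 2α), α = 1 by default. The Bernoulli event
  model matches binary presence features; a multinomial variant is
  deliberately not the default.
* **Gain-ratio decision tree** (authored here, C4.5-style): binary splits
  on feature presence chosen by gain ratio = information gain ÷ split
  information; candidate splits must leave ≥ `min_leaf` (default 2)
  documents in each child and have positive gain; recursion stops at
  purity or when no candidate remains. Error-based post-pruning and
  missing-value handling of full C4.5 are out of scope: features here are
  binary and complete, which is where those mechanisms matter least.
* **Polynomial-kernel SVM**: one-vs-rest with kernel (x·y + 1)^degree
  (coef0 = 1, γ = 1, so the kernel is the classic inhomogeneous
  polynomial and invariant to dataset duplication), delegated to
  scikit-learn's SVC behind the shared contract. Defaults degree = 1,
  C = 1 are declared, not inferred — the source protocol names the kernel
  family but no hyperparameters.

Ties everywhere (posterior ties, leaf majorities, one-vs-rest decision
ties) break to the first class in class order, which is the corpus's
first-appearance label order; this is unit-tested.

Models serialize to a documented JSON schema (naive Bayes, tree) or via
joblib (SVM).

## Evaluation protocol

Stratified tenfold cross-validation (per-class fold sizes differ by ≤ 1;
unstratified available by flag), 90% train / 10% test per fold. The
report pools all test predictions into a single confusion matrix —
pooling was chosen over averaging per-fold metrics because it keeps the
micro identity "accuracy = class-weighted mean recall" exact — and also
retains per-fold metrics for the t-tests. Per-class precision, recall and
F use the 0-denominator → 0 convention; the "Average" row is the macro
(unweighted) mean, a convention declared rather than fitted since
published per-topic tables are often ambiguous about their aggregation.

Repeated comparison runs perform 10 repetitions of tenfold CV; the fold
seed of repetition r is shared across all configurations, giving a paired
design. The paired t-test is one-sided for mean(b − a) > 0 with sample
standard deviation and n − 1 degrees of freedom; degenerate cases are
pinned (all-zero differences → t = 0, p = 0.5; zero spread with nonzero
mean → ±∞, p ∈ {0, 1}). The repetition scheme re-runs tenfold CV on the
full corpus with a fresh fold seed each time; bootstrap subsampling
between repetitions is not used.

A frequency-threshold sweep re-runs FS1 CV per threshold. With an
absurdly large threshold the feature space is empty; the pipeline then
degenerates gracefully to majority-class prediction from the training
fold.

## Synthetic study conditions

The generator emulates a three-board breast-cancer forum. Defaults:
n = 4041 messages at class proportions 1224 : 991 : 1826
(treatment / emotional support / survivorship); class-conditional Poisson
message lengths (means 45 / 28 / 50 emission events — treatment and
survivorship posts run longer than well-wishes); a shared 600-word
Zipf-weighted background vocabulary plus a 15% function-word rate; a 15%
class-signature rate over 40 signature words and 5 two-word signature
phrases per class (Zipf within the signature, emitted atomically so
bigram/trigram features carry signal); domain-term injection highest in
the treatment-like class (10% / 2% / 5% per event over 40 class-specific
terms, one fifth of them bigrams) and sentiment-term injection highest in
the emotional-support-like class (2% / 10% / 5% over 25 lemmas). All
non-shared vocabularies are disjoint across classes and families, which
keeps the emission events recoverable from the token stream; the
Bayes-optimal oracle therefore scores the exact posterior
log P(c) + log Poisson(n; μ_c) + Σ log p_c(event) by Monte Carlo on fresh
draws and reports a standard error.

Named presets define the other study conditions:

* `strong_signature_config` (n = 1000, signature rate 0.30): clearly
  separated topics, Bayes-optimal accuracy ≈ 1; used to require ≥ 0.9
  pooled tenfold accuracy from all three classifiers.
* `domain_signal_config` (n = 800, signature rate 0.02, 80 domain terms
  per class at rates 10% / 4% / 7%, no sentiment injection, equal
  lengths): the class signal lives almost entirely in many
  individually-rare domain terms, each below the n-gram frequency
  threshold, so FS1 is nearly signal-free while FS2 separates the
  classes — the construction behind the FS1 < FS2 comparison experiments.
* `no_signal_config`: identical emission distributions and lengths across
  classes; the Bayes-optimal and any classifier reduce to the majority
  class.

What the generator does **not** emulate: English syntax, thread/reply
structure, spelling variation, topic drift within a message, correlated
token burstiness, and polysemous lexicon matches. Passing tests
demonstrate that the pipeline's machinery is correct and that the
protocol detects feature-family contributions it was designed to detect;
they do not certify accuracy levels on real forum text, where class
overlap is far larger (real per-topic F-measures in this problem sit
near 0.8, not the near-1 values the cleanly separable synthetic defaults
produce).

## Numerical choices and problem sizes

Information gain is computed vectorized over columns with tiny negative
round-off clipped at 0; oracle tests require agreement with a direct
evaluation of the definition to 1e−12. Strict inequalities at the three
published boundaries (IG > 0.0025, subjectivity > 0.5, frequency ≥
threshold with "≥" as the declared convention for the unstated boundary)
are each unit-tested. Test and acceptance runs use n = 300–4041 corpora,
10 folds, 10 repetitions and 2000 Monte-Carlo oracle draws — sizes chosen
so the full suite and the acceptance script each complete in about a
minute on one core while keeping multinomial/Monte-Carlo noise well
inside the asserted tolerances.

## Known limitations

Tokenization is English-centric and has no sentence segmentation,
negation handling or spell correction. Lexicon matching is surface-form
(no lemmatization beyond lowercase, no word-sense disambiguation, no CUI
normalization). The C4.5 implementation omits post-pruning. The CLI's
`compare` pairs feature sets only; classifier-vs-classifier comparisons
use the library (`repeated_cv` + `paired_t_test`) directly.
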