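# Methods

## Problem and model

`littriage` treats literature triage as binary ranking: each abstract is
either *useful* for product risk assessment (reports or characterizes a
safety signal) or *non-useful*, and the deliverable is an ordering of
unread abstracts by a classifier's confidence of usefulness. Ranking, not
hard classification, is the contract: an evaluator reads down the list and
stops when the yield drops, so the operative error measure is AUC (the
probability a random useful article outranks a random non-useful one) and
the decile lift chart, not accuracy at a threshold.

## The mining chain

Title and abstract are concatenated and processed in a fixed order:

1. **Tokenize** — maximal runs of Unicode letters/digits, lowercased.
   Hyphenated forms split; pure-digit tokens are dropped (numbers are not
   reusable predictors); Greek letters survive as single-character tokens
   since abstracts usually carry spelled-out or symbolic forms directly.
2. **Stem** — classical Porter suffix stripping, hand-implemented
   (`stemming.py`). The classical algorithm is one pass and not a
   projection (e.g. `agreed → agre`, while `agre → agr`); because
   predictors are equivalence classes, the public `stem()` iterates the
   pass to its fixpoint so stemming is idempotent. Root strings are
   internal feature names only; only the induced equivalence classes
   matter for classification.
3. **Stop words** — removal against a shipped ~130-token English list.
4. **Synonyms/acronyms** — token-wise replacement by canonical form
   (British→American spellings, common pharmacology acronyms). The map
   must be chain-free; this is validated at load.
5. **Phrases** — leftmost-maximal, non-overlapping multiword terms joined
   with underscores (`tumor necrosis factor → tumor_necrosi_factor`).

All resources are stemmed at load time so lookups happen in the same
space as the (stemmed) token stream; phrase and multiword entries are
stemmed component-wise. The chain runs stop-word removal before synonym
merging; for disjoint resource sets the two commute (tested).

Predictors are chain-surviving terms occurring in at least
`min_document_frequency` documents (default 2: singletons are noise and
inflate the lexicon). Terms on the general-term list are *general*
(drug-class-agnostic); all others are *specific*. The shipped general
list is a starter (~85 safety/design/regulatory terms); a curated list in
the same one-term-per-line format replaces it via `load_resources`.

## Feature weighting

Three weightings on the document × predictor matrix:

* occurrence `n_ij`; binary `1[n_ij ≥ 1]`;
* TF-IDF: `TF_ij = n_ij / Σ_k n_kj` with the denominator the document's
  *full* post-chain token count recorded before lexicon pruning, so TF is
  a true within-document proportion; `IDF_i = log10(N/n_i)`. Log base 10
  is a convention (any base is a positive scalar on all features) and is
  configurable.

The IDF table and term order are fitted on the training corpus and
frozen; validation/transfer documents are weighted with the stored table
(`transform_new`), never refitted — refitting per set would make features
incomparable across sets. Zero-token documents produce all-zero rows, not
errors. No length normalization is applied by default.

## Classifiers and confidence

scikit-learn provides the fitters behind the `models` surface. The
production configuration is an RBF-kernel SVM; its signed decision value
is the confidence (monotone in distance from the hyperplane; probability
calibration would not change the ranking and is omitted). Logistic
regression and naive Bayes expose the useful-class posterior, k-NN the
neighbour vote fraction. Naive Bayes is multinomial on count-like
weightings and Gaussian on TF-IDF. Hard labels, where needed, use
threshold 0 (decision values) or 0.5 (posteriors/votes).

Defaults: `C = 1.0` (a legacy `C = 0` sentinel meaning "choose
automatically" maps to 1.0 with a warning, since a zero soft-margin
penalty is undefined) and `gamma = 'scale'` (1/(n_features·Var)). A fixed
numeric kernel width is scale-sensitive — TF-IDF values shrink as the
lexicon grows, and a width of 1.0 on such features makes the kernel
nearly constant — so the variance-scaled width is the robust default;
any positive numeric gamma can be set to reproduce fixed-width setups.

## Selection for the specific system

Kennard–Stone picks maximally mutually dissimilar documents (Euclidean
distance on the fitted weighting): seed with the most distant pair, then
repeatedly add the point maximizing its minimum distance to the selected
set. Ties break to the lowest row index for determinism; the greedy
sequence is nested, so one run serves all training-set sizes.

Because useful articles are a minority, a Kennard–Stone selection can be
single-class — with two documents this is in fact the usual outcome on
the synthetic corpora. `bootstrap_specific` treats a single-class
selection as an error (the workflow should switch selection method);
`training_size_experiment` instead reports the row with `trained=False`
and AUC 0.5, the exact AUC of the constant-confidence ranker that a
single-class training set induces. The alternative selection,
`confidence_extremes`, takes the documents a general system is most and
least confident about, which strongly favours capturing both classes in a
20-document labeling budget.

The bootstrapped specific system re-extracts its lexicon and IDF from the
~20 selected documents only (all predictor categories); the
training-size experiment, whose selections go down to 2 documents, trains
on rows of the dataset-A-fitted matrix instead, since a re-extracted
min-df-2 lexicon from 2 documents is frequently empty.

## Evaluation

AUC is computed by the Mann–Whitney rank-sum with midrank ties — exactly
the all-pairs count with half credit for ties, in O(n log n); tests
verify exact agreement with exhaustive pair counting. Lift charts sort by
confidence (ties by doc_id), cut into near-equal bins with extras
front-loaded, and report per-bin useful counts plus cumulative
percentages against the diagonal. Numbers (TSV/JSON) are the product; the
matplotlib rendering is a convenience.

## Synthetic corpora: what they emulate, and what not

The generator plants the structure the systems assume: a minority useful
class (prevalence 0.175), and a vocabulary of 60 general signal terms, 40
class-specific signal terms per drug class, and 400 noise terms. Useful
documents oversample their signal terms by a multiplicative enrichment
factor (default 5); non-useful documents draw uniformly. Document length
is negative binomial (mean 120 post-chain tokens, shape 20), roughly a
title plus a 100–150-word abstract. Each drug class *activates* a random
70% subset of the shared general vocabulary: useful articles of different
classes express overlapping but non-identical general signals, which is
what makes a general system transfer imperfectly to unseen classes —
mirroring the observation that new drug classes carry general predictors
the training class never exhibited. Generated terms are consonant-suffixed
pseudo-words that are stemmer fixpoints and never stop words, so the
chain passes them through unchanged.

What the generator does **not** emulate: natural language (documents are
bags of tokens — sufficient because the pipeline only consumes term
counts), label subjectivity, topic drift, MeSH structure, or realistic
vocabulary sizes. The planted signal is much cleaner than real abstracts:
held-out AUCs on synthetic corpora sit near 0.99, far above what labeled
pharmacovigilance corpora yield. Passing tests therefore demonstrate
correctness of the machinery and the direction of the documented effects
(TF-IDF ≥ binary; performance grows with training size; transfer to
unseen classes degrades; a 20-document specific system beats a
transferred general system) — not absolute performance on real data.

One calibration subtlety: training on *permuted labels* of a
signal-bearing corpus is not a chance-level control for kernel-SVM
confidences, because useful documents keep systematically larger feature
norms and decision values correlate with norm regardless of labels. The
valid null is the enrichment-1 corpus (no label–term association
anywhere), which the calibration tests use.

## Problem sizes and numerical choices

Tests and the acceptance script use synthetic corpora of 500–1000
documents (500 per class in the five-class transfer experiment), 70/30
stratified splits (then 2:1 for train/test where needed), 10–20 generator
seeds per trend experiment, and training sizes {2, 20, 36, 74, 112} for
the Kennard–Stone experiment. Stratified splitting is per-class
shuffle-and-cut with largest-remainder apportionment, so per-class counts
are within one document of exact proportionality and identical seeds give
bit-identical partitions. Exact-equality oracles (TF-IDF, AUC,
Kennard–Stone, lift) are checked to 1e-12 relative. Ties everywhere break
deterministically: doc_id ascending in rankings and lift bins, lowest
index in Kennard–Stone.

## Known limitations

* The shipped resource lists are small open starters, not the curated
  proprietary lists a production deployment would use.
* The general-predictor list must be maintained as new drug classes are
  triaged; the package takes it as input and does not update it.
* Only titles+abstracts are mined; full-text and MeSH/UMLS features are
  out of scope.
* The single bootstrap round is implemented; iterative active learning is
  not.
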