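# Methods

## Problem and model

`pktriage` addresses binary triage of PubMed records: does a publication
report newly estimated in-vivo pharmacokinetic (PK) parameters
(Relevant) or not (Not Relevant — no estimates, reviews, or parameters
quoted from other studies)? Only fields available for essentially every
record are used: title, abstract and PubMed metadata (authors, journal,
publication types, keywords, MeSH descriptor names, chemical substance
names, affiliations). Full text and tables are deliberately out of
scope, which makes the classifier applicable to records where only the
citation is available.

The classifier is a gradient-boosted decision-tree ensemble,
H_L(x) = Σ_{l=1..L} η · w_l · f_l(x), trained to minimise average
cross-entropy. The per-learner weights w_l are not a user-visible knob:
in the boosting engine (XGBoost, driven through its native train API)
they are absorbed into the fitted leaf values of each tree. All engine
hyperparameters not listed below stay at the engine's documented
defaults, recorded in each run manifest.

## Document representation

**Normalisation chain** (title/abstract, in order): rule-based
tokenisation → chemical masking → lower-casing → stripping punctuation
characters inside tokens (tokens reduced to nothing are dropped) →
replacing all-digit tokens with `##` → stop-word removal → Porter
stemming. Ordering rationale: masking operates on raw surface forms, so
it precedes normalisation; stemming is last so stop-words are matched in
their dictionary form. The digit test runs after punctuation stripping,
so `3.5` → `35` → `##` — the most aggressive consistent reading for
decimal tokens; both the digit collapse and stemming are switchable.
The chain is idempotent apart from stemming (Porter is not idempotent:
e.g. a second pass maps `ti` no further but `relate` → `relat`).

The default tokeniser is a documented rule set: split on whitespace and
punctuation boundaries, keep hyphenated terms (`half-life`) and decimal
numbers (`5.2`) whole, emit other punctuation as single-character
tokens. The tokeniser is pluggable for external scientific-text
tokenisers. The Porter stemmer is implemented in-package from the
algorithm's original definition (without the two later departures) and
is validated against the algorithm's published example words. The
stop-word list (318 English words) and a small chemical-name lexicon are
shipped frozen under `src/pktriage/data/` so results cannot drift with
library versions.

**Chemical masking** replaces every detected chemical mention span with
the single token `@CHEM` (`##` being reserved for digits), preventing
the model from keying on individual drug names. The default recogniser
is a deterministic longest-match dictionary masker over the shipped
lexicon; a statistical NER adapter can be plugged in behind the same
span contract.

**Bag of words.** Unigrams (optionally bigrams/trigrams, joined with
`_`) are generated from the normalised text tokens; n-grams are not
generated from metadata. Metadata fields contribute single namespaced
terms (`mesh_term=Rats`, `journal=Clin Pharmacokinet`) with no further
processing. Text and metadata terms share one vocabulary and one
`min_df` threshold (default 20 documents); columns are ordered
lexicographically so layouts are deterministic. Each document vector
holds term counts divided by the document's **in-vocabulary** term
total, so every non-empty row is exactly L1-normalised; the alternative
denominator (all tokens including filtered ones) would break the stated
norm and is intentionally not used. The preset
`OPTIMAL_FIELDS = (title, abstract, mesh_terms, publication_types)` is
the best-performing field combination for this task.

**Embedding block.** Token-level providers return one d-vector per
token, defined as the element-wise sum of an encoder's last four hidden
layers; document-level providers return one vector per document. Mean
pooling concatenates the per-field token means (dimension 2d; 1536 at
d = 768); mean+min&max pooling concatenates per-field mean, element-wise
min and max (6d; 4608). A field with no tokens contributes a zero
sub-vector (an alternative — duplicating the title mean — exists but is
not the default). Tokens fed to embedding providers are the raw
tokenised surface forms, not the stemmed/masked BoW tokens, since
transformer encoders expect surface text. The package ships a
deterministic hashing provider (each token's vector is a hash-seeded
normal draw, memoised process-wide); real encoders are optional adapters
behind the same contract and are never required by the tests. Sequence
truncation for real adapters follows the encoder's maximum length.

## Classifier and weighting

Defaults: η = 0.1, max 2000 rounds, early-stopping patience 100,
max_depth 4, colsample_bytree 1.0, decision threshold 0.5. Sample
weights are n/n_class — at prevalence p the positive class gets 1/p, so
20% prevalence gives the factor five. Inside the estimator the weights
are mean-normalised before being passed to the engine: the engine's L2
leaf penalty makes raw predictions sensitive to the absolute weight
scale, and normalisation makes them exactly invariant to constant
rescaling, which is the behaviour a frequency-derived weighting should
have. Early stopping maximises F1 at threshold 0.5 on the provided dev
set (the threshold for the stopping metric is a package choice); a dev
set without positives is rejected, since F1 is undefined as a stopping
signal. The returned ensemble is truncated to the best-dev-F1 round.

## Evaluation protocol

Each bootstrap iteration draws a stratified 60/20/20
train/dev/test split, fits on train with dev early stopping, and records
Relevant-class precision/recall/F1 on test. Iterations are seeded
independently from a master seed via a counter, so any single iteration
is reproducible in isolation and two configurations run with the same
master seed see identical splits. Summaries report the median and the
empirical 2.5th/97.5th percentiles (linear interpolation between closest
ranks — numpy's default percentile rule) per metric, plus the F1
interquartile range ("IQV") on the percent scale. Note "IQV" here is
defined as the 75th minus 25th percentile of the F1 samples.

Cohen's kappa is standard binary kappa,
K = (p_o − p_e)/(1 − p_e), with p_e from the product of the annotators'
marginals; it errors at p_e = 1 where K is undefined. Multi-annotator
agreement is summarised as the mean ± SD of pairwise kappas rather than
a Fleiss-style coefficient.

Grid search enumerates the full Cartesian grid (min_df 2→512 doubling,
max_depth 2→64 doubling, colsample_bytree 1/3→1 in thirds; 162 points)
with stratified five-fold CV; inside each fold the held-out part doubles
as the early-stopping dev set, since the protocol has no third split
within CV. Ties are broken toward smaller min_df, then smaller
max_depth, then larger colsample_bytree (prefer the simpler model).

## Synthetic corpora

The generator emulates exactly the structure the classifier exploits,
with defaults frozen as the package's study conditions:

- 20% Relevant prevalence, assigned by exact count (not Bernoulli) so
  stratified-split edge cases are deterministic;
- PK signal terms (including multi-word terms such as "volume of
  distribution", which exercise the n-gram path) injected independently
  into Relevant abstracts with probability 0.9 and into Not Relevant
  abstracts with probability 0.05;
- a weaker title echo: with probability 0.5 a Relevant title carries a
  "Pharmacokinetics of <term> in <species>" headline (0.02 for
  Not Relevant). The shared carrier token matters: a design that echoes
  only one randomly chosen rare term per title leaves every title term
  below realistic min_df thresholds, and the title would carry no
  learnable signal at all — unlike real PK titles, which are
  headline-stereotyped. The 0.5 rate places the title-only pipeline
  roughly midway between chance and the full pipeline, mirroring the
  observed ordering title < title+abstract < optimal fields;
- numeric parameter-value tokens at higher rate in Relevant abstracts;
- 13% of abstracts missing entirely — removing abstract-borne signal,
  the dominant realistic cause of false negatives;
- "Review" publication type on 30% of Not Relevant records, a mildly
  label-correlated MeSH descriptor, and background text drawn from a
  Zipf-distributed synthetic vocabulary (500 words, exponent 1.1), kept
  licence-clean and download-free.

What passing tests on these corpora do **not** show: performance on real
abstracts (real language is not Zipf noise; real signal terms are
paraphrased, ambiguous and entangled with negation), robustness of real
transformer embeddings (the hashing stub has no semantics — it can only
memorise token identity), or the true PubMed joint distribution of field
availability. The synthetic results validate the machinery, not the
deployed accuracy.

## Numerical and design choices

- Problem sizes: behavioural checks use n = 600 documents and 50
  bootstrap iterations; analytic and property checks run at the sizes
  stated in their tests. These are the package's own desk-scale study
  conditions.
- Percentile rule: linear interpolation (documented above); tolerance
  for L1 normalisation 1e−12; pooled-block comparisons at float64.
- Degenerate metrics (no predicted or no true positives) return 0
  rather than NaN, and are logged.
- Duplicate PMIDs across parsed files: last record wins (update-file
  semantics), logged. Citations lacking a PMID or title are skipped
  with a warning; structured abstracts are concatenated in document
  order; MeSH qualifiers are dropped.
- Label strings are normalised case-insensitively with whitespace
  collapsed ("Not Relevant" ≡ "NotRelevant").
- Seeds are mandatory on every stochastic CLI command, and every
  artefact-producing command writes a JSON manifest (config, seed,
  vocabulary hash, versions) sufficient to re-run it.

## Known limitations

- The Porter stemmer follows the original algorithm; stemmers with the
  later revisions (e.g. Snowball) differ on a handful of suffixes.
- The dictionary chemical masker only finds lexicon entries; recall on
  real chemical mentions requires an NER adapter.
- Probabilities are not calibrated; the 0.5 threshold is a decision
  default, not a calibrated operating point.
- `predict` on corpora whose field distribution differs strongly from
  training (e.g. all abstracts missing) degrades gracefully but silently;
  the stats command exists to check availability first.
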