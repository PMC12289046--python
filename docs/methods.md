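# Methods

## Problem and formulation

Retrospective data harmonization merges datasets collected by different
cohort studies.  Its first, labor-intensive step is *variable matching*:
deciding, for each variable of a source study, which variable(s) of a target
study measure the same construct.  `varmatch` treats this as a ranking
problem.  For every source variable, all target-study variables are
candidates; each candidate receives a match score and the candidates are
ranked by descending score.  A useful system places the true counterpart(s)
near the top of the list so a curator inspects a handful of candidates
instead of the whole dictionary.

Matching uses only data-dictionary metadata — never participant-level
values.  Each variable contributes three text channels:

1. **label** — the human-readable variable label;
2. **sheet** — the description of the data sheet containing the variable;
3. **label + keywords** — the label concatenated with the derivation rule,
   or with keywords extracted from it when the rule is long.

## Text preparation

**Keyword extraction.**  Derivation rules vary from a few words to
paragraphs.  Rules of 20 or fewer words are used verbatim; longer rules are
condensed to at most 15 words: candidate n-grams (lengths 1–2) are embedded,
ranked by cosine similarity to the embedding of the whole rule, and selected
greedily in descending score with already-selected words removed, stopping
at the word budget.  Selection order is preserved; every output word occurs
in the rule.  The n-gram range and budget are configurable; the
deduplication rule is ours (overlapping keyphrases otherwise waste the
budget on repeated words).

**Fuzzy normalization.**  Fuzzy matching sees lowercased text with
punctuation removed, English stop words dropped (a frozen 179-word list
shipped with the package so results do not drift with external library
versions) and Porter-stemmed tokens.  The pass is applied to a fixed point:
Porter stemming alone is not idempotent ("employment" → "employ" →
"emploi", and a stem can land on a stop word, e.g. "one" → "on"), and we
want normalization to satisfy f(f(x)) = f(x) so both comparison sides always
see fully reduced tokens.  In practice the fixed point is reached in two
passes.  Embedding channels always receive the raw text; only fuzzy matching
uses the normalized form.

## Similarity methods

Five methods score every pair on every channel, giving 15 similarity
features.

**Embedding channels.**  A backend registry maps identifiers to sentence
embedders.  Pretrained transformer backends (E5-large-v2, all-mpnet-base-v2,
all-MiniLM-L12-v2, BioLORD-2023) are registered and used when the optional
`embeddings` extra is installed; E5 inputs get the `"query: "` prefix on
both sides (symmetric similarity usage).  The default, always-available
family is `offline-hash`: a seeded character-n-gram hashing embedder.  Text
is decomposed into character n-grams (plus word unigrams), each feature is
hashed (keyed blake2b, never Python's randomized `hash`) into one of
192–384 signed buckets, and the count vector is L2-normalized.  Four
registered variants differ in n-gram sizes, dimensionality and hash salt,
giving the ensemble genuinely different lexical views.  Hash embedders are
deterministic across platforms and need no model download; they capture
lexical, not semantic, similarity — a limitation discussed below.  Pair
similarity is the cosine; zero-norm vectors (empty text) score 0.
Embeddings are cached per distinct string, so each text is embedded once per
backend.

**Fuzzy channel.**  The token-set ratio on the 0–100 scale: tokenize on
whitespace, deduplicate, sort; with I the sorted token intersection and
D1/D2 the sorted differences, form s0 = join(I), s1 = join(I + D1),
s2 = join(I + D2) and return 100 × the maximum normalized indel similarity
over (s0,s1), (s0,s2), (s1,s2), where
sim(x,y) = 1 − indel(x,y)/(|x|+|y|).  The indel distance is computed as
|x| + |y| − 2·LCS(x,y) with a vectorized longest-common-subsequence row
recurrence; the test suite checks it against an independent insert/delete
grid dynamic program.  If either token set is empty the score is 0 by
convention.  A perfect 100 occurs exactly when one token set contains the
other.

## Feature vector

Each source–target pair carries 21 features: the 15 similarity scores
(5 methods × 3 channels, named e.g. `Fuzzy_on_label`, `HashA_on_label_key`)
plus 6 metadata features — label word count, derivation-rule word count and
rule absence for each side (`Label_len_src`, `Derive_info_len_tgt`,
`Derive_info_null_src`, …).  Word counts use whitespace tokenization of the
raw text.  Booleans are encoded 0/1; no scaling is applied (tree ensembles
are scale-invariant).  The binary class label is 1 iff the pair is in the
ground-truth match table.

## Ranking and evaluation

`rank_candidates` orders candidates by descending score.  Equal scores form
a tie block; every member receives the median of the positions the block
occupies (three candidates at positions 4–6 all get rank 5) — identical to
average-rank assignment, computed via `scipy.stats.rankdata`.  Ranks
therefore sum to N(N+1)/2 and may be fractional.

For a source with true target set T, R_hit is the smallest median-resolved
rank among T.  HR-n is the fraction of evaluated sources with R_hit ≤ n
(strict: a tie-block rank of 30.5 is not a top-30 hit); MRR is the mean of
1/R_hit, with fractional R_hit used as-is.  Evaluation runs only on sources
that have at least one true target.

## Ensemble protocol

One trial:

1. **Split** the matched sources 4:1 into train/test *by source variable*
   (floor(0.8·N) on the training side, matching 277/70 at N = 347), so no
   pair involving a test source can appear in training.
2. **Down-sample negatives**: a training source with m positive pairs
   contributes m·k distinct negatives (k = 200) drawn uniformly without
   replacement from the targets not matched to it — excluding *all* of its
   true targets, and deduplicated within the source, so multi-match sources
   never receive contradictory labels.  When the pool is smaller than m·k
   (small target studies) all of it is taken, with a warning.  The test set
   keeps every negative: each test source is paired with the entire target
   dictionary.
3. **Tune and train** a Random-Forest classifier by grid search with
   grouped 5-fold cross-validation: folds are formed over source variables
   (never pairs), each fold must contain at least one positive, and the
   validation metric is a ranking metric (HR-30 by default, MRR available)
   computed within each fold over each source's down-sampled candidate set.
   The grid point with the highest mean validation metric wins, ties going
   to the first point in grid order; the winner is refit on the full
   training set.
4. **Predict and rank**: the positive-class probability of each test pair is
   the match score; ties are resolved by the median-rank rule downstream,
   never by target-name order.

The default grid is deliberately small: trees {300, 500} × depth {10}.  Two
ranking-specific considerations drive it.  The forest's probability is a
vote fraction, so its granularity is 1/n_trees; ranking a candidate list a
few hundred long needs at least ~300 trees or equal-probability tie blocks
swallow the top of the list.  And a depth cap keeps leaves impure, so
weak-signal true pairs receive graded (small but nonzero) probabilities
instead of collapsing into the all-zero tie block at the bottom, where the
median-rank rule buries them.  `FULL_GRID` provides the exhaustive sweep
(trees {100, 300, 500} × depth {∞, 10, 20} × criterion {gini, entropy} ×
min-split {2, 10} × features {√p, 0.5p}) for users who want it.

The experiment loop repeats this over n deterministic trials (per-trial
seeds derive from the master seed and trial id) and also evaluates:

* every similarity feature alone as a **single-channel baseline** ranker;
* a **label-permuted control**: the chosen forest retrained on shuffled
  training labels.  Note its scores remain a function of the features, and
  features correlate with the truth, so this control is *not* expected to
  sit exactly at the analytic chance level;
* a **random-ranking control**: candidates ranked by iid uniform scores and
  judged against one designated true target per source, for which
  E[HR-n] = n / n_targets exactly.  This is the control the test suite
  compares with the analytic baseline (within three binomial standard
  errors).

With the master seed fixed, the entire experiment — features, splits,
sampled negatives, fitted forests, probabilities, reports — is
bit-reproducible.

## Across-trial analysis

**Model comparison** uses two-sided paired t-tests over per-trial metric
values, with a t-based 95% confidence interval on the mean difference.
Zero-variance differences are reported as p = NaN with an explicit
degenerate-variance flag rather than raising.

**Permutation importance**: for each feature, its column is shuffled
globally across all held-out pairs (5 repeats by default), pairs are
re-scored and re-ranked, and the decline of each metric (HR-5, HR-10, MRR
by default) from the unpermuted baseline is averaged over repeats, then
over trials.  Negative declines are possible and meaningful.  Two
aggregation views are produced: mean decline per feature, and the mean of
within-trial ranks (ties averaged).

**Feature ablation** partitions the 21 features into embedding-derived
(12), fuzzy-derived (3) and other/metadata (6) groups, reruns the whole
experiment with one group removed under identical seeds, and pairs the
comparison trial by trial.

## Synthetic corpus

Because real cohort dictionaries are typically access-restricted, the
package generates paired dictionaries with known ground truth.  The
generator emulates the statistical character reported for real dictionary
pairs: source labels longer than target labels (means 11.3 vs 8.5 words),
derivation rules mostly missing on the source side (70%) but present on the
target side (90%), one-to-many matches for ~20% of matched sources (2–3
true targets), category-structured sheets (demographics, anthropometrics,
questionnaire items, costs, time-to-event) with divergent sheet wording,
and derivation rules synthesized from clause templates that mention the
underlying concept.

Matched variables derive from a shared concept (base phrase + qualifier)
through independent noise on each side: synonym swap (0.60), token drop
(0.30), token move (0.25), abbreviation (0.35).  Corruption spares the
concept's base tokens — real studies rename and trim qualifiers far more
often than the construct name itself — and abbreviation on the target side
is rendered parenthetically ("body mass index (BMI)"), as commonly seen in
real dictionaries, so an abbreviation always leaves a lexical anchor.  Most
synonym fixtures share a head token with the original; a few fully disjoint
renamings (sex/gender) are kept for realism.  The noise levels are
calibrated so that individual similarity channels achieve HR-30 roughly in
the 0.78–0.93 range on the standard corpus — the difficulty regime reported
for single methods on real dictionary pairs — leaving headroom that only
fusion across channels can close.  The concept inventory (bases and
qualifiers) is constructed so that no two concepts have nested normalized
token sets; under zero noise every true pair is therefore the unique
perfect token-set match, and the generator's zero-noise limit yields
identical source/target labels with HR-1 = 1.

Distractor targets come from held-out concepts, so negatives are plausible
(same vocabulary, same sheets) but never accidentally correct.  Everything
derives from a single seed; identical configs produce byte-identical
output.

**What the corpus does not emulate** — and hence what passing tests do not
show about real data: true semantic divergence (translations, paraphrases
with no shared tokens) that pretrained embedders would bridge but hashing
embedders cannot; ambiguous or underspecified variable definitions, the
dominant error source in real matching; multilingual text; value-level
compatibility.  Results on the standard corpus validate the pipeline's
mechanics (feature construction, learning, ranking, evaluation), not
real-world matching accuracy.

## Problem sizes

The standard corpus is 60 source × 240 target variables (≈54 matched
sources, ≈65 truth pairs).  The standard experiment runs 10 trials with
k = 200 (capped at the 237–239-target pool, so training effectively sees
every negative of each training source), the default 2-point grid and
grouped 5-fold CV.  Unit tests use a 14 × 40 corpus.  These sizes are the
package's test defaults; all of them scale via configuration.

## Numerical choices and edge cases

* Cosine of a zero-norm vector is 0; embedding a non-empty string always
  yields a unit vector.
* Token-set ratio with an empty side is 0; with both sides empty, 0.
* NaN candidate scores are an error naming the offending target.
* An all-stop-word label normalizes to the empty string; its fuzzy scores
  are 0 and its embedding channels still see the raw text.
* Long-to-wide widening of a questionnaire sheet replaces the
  (question-number, score) variable pair with one synthetic variable per
  distinct question (`SCORE_3` style names; keys containing the `_`
  separator are sanitized with a warning); applying the transform to an
  already-widened dictionary is a no-op.  Visit-indexed longitudinal
  variables are deliberately *not* widened: when visit schedules align
  across studies, visit-number alignment already solves time-dependent
  matching.
* Seeds: every stochastic step draws from `numpy` generators seeded with
  (master seed, trial id, stage) tuples; forest seeds are reduced below
  2^31.

## Known limitations

* The offline hashing embedder measures lexical overlap only; on real
  dictionaries the pretrained backends should be used.
* With few training positives (small matched sets) the forest's advantage
  over the best single channel shrinks; the protocol reports both so the
  comparison is always visible.
* Grouped CV selects hyperparameters on down-sampled within-fold candidate
  sets, which compresses metric differences between grid points; the small
  default grid reflects that.
* The manual curation workflow that produces ground-truth match tables is
  out of scope; the package consumes a finished 2-column table.
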