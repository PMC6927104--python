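# Methods

## The similarity model

`cdemap` treats the mapping of a CDE to a BRIDG class as nearest-class
retrieval under a learned lexical similarity. Every comparison between
two CDEs reduces to six attribute-phrase comparisons (CDE long name,
object class, property, value domain long name, representation term,
question text — always in that order), each producing a similarity
`s_i ∈ [0, 1]`, combined as the weighted sum `s = Σ wᵢ sᵢ` with the
weights constrained to the probability simplex. The model is therefore a
single-layer 6×1 linear network whose only free parameters are the six
weights.

### Tokenization

Phrases are lowercased, every non-alphanumeric character becomes a
separator, and separator runs collapse. This reproduces the intended
behaviour on sentence-form question texts (a trailing `?` does not
create a token; "What" matches "what") while keeping digits intact.
Hyphenated terms split into their parts — a choice, not a necessity; no
stemming or synonym expansion is applied anywhere.

### Word and attribute similarity

Word similarity is `1 − d/l` with `d` the unit-cost Levenshtein distance
(computed by edlib) and `l` the longer word's length; it is symmetric,
lies in [0, 1], and equals 1 exactly for (case-folded) identical words.
It is undefined for two empty words.

For two phrases, the full |a|×|b| word-similarity matrix is reduced
greedily: take the current global maximum, record it, delete its row and
column, repeat until one dimension is exhausted. Ties break to the
smallest row index, then the smallest column index (row-major `argmax`),
which makes the reduction deterministic; the recorded list is
non-increasing by construction and has length `min(|a|, |b|)`. The
attribute similarity is the fraction of recorded pairs whose similarity
meets the word-similarity threshold (compared with `≥`). The threshold
(default 0.8, conventional grid 0.6–1.0) is fixed for the life of a
model.

Consequences accepted for fidelity to this construction:

* a phrase scores 1.0 against any superset phrase (the list length is
  the *shorter* phrase's length), so subset long names inflate;
* an empty phrase scores 0 against anything, including another empty
  phrase — absent text is treated as carrying no evidence of a match.

## Weight learning

For an anchor record in class *c*: `s_avg` is its mean overall
similarity to the other members of *c*, and `s_avg_other_cls` its mean
overall similarity to every record outside *c*. With
`s_max = max(s_avg, s_avg_other_cls)`, the anchor's error is
`½ (s_max − s_avg)²` — zero exactly when the own class already
dominates — and a non-zero error triggers the delta-rule step
`wᵢ += η · (s_max − s_avg) · s̄ᵢ`, where `s̄ᵢ` is the anchor's mean
within-class attribute-similarity vector, followed by renormalization
onto the simplex.

Decisions taken where the procedure was genuinely open:

* **Renormalization schedule.** The simplex constraint is restored after
  *every* update by dividing by the weight sum. The additive step is
  non-negative, so weights stay non-negative and the constraint holds to
  1e−9 throughout (a per-run invariant, not a final fix-up).
* **`s̄ᵢ` as a mean, not a sum.** Averaging over the anchor's
  within-class pairs keeps the step size independent of class size; the
  summed form is recovered by scaling η.
* **Anchors.** By default every class member serves as anchor once per
  pass (`anchor_mode="all"`); `anchor_mode="first"` (one anchor per
  class per pass) is available but discards most of the training signal.
* **Pass order.** Classes are visited from fewest to most members, ties
  broken lexicographically, so runs are reproducible.
* **Stopping.** At most 50 passes (default) with η = 0.05; training
  stops early when the total per-pass error changes by less than 1%
  relative — by 50 passes the error trace typically only fluctuates at
  that level. A corpus whose every anchor already satisfies
  `s_avg ≥ s_avg_other_cls` is a fixed point: uniform weights survive
  unchanged and the error trace is all zeros.

A noteworthy property of this rule: weight flows toward attributes with
a high within-class mean similarity *among the anchors that fire*
(those with `s_avg < s_avg_other_cls`). It rewards attributes that are
consistently phrased within a class rather than attributes with the
largest within/between contrast; the question-text weight tends to end
up slightly highest on templated corpora precisely because a full
sentence shares many words within a class.

The attribute similarities between record pairs do not depend on the
weights, so the trainer precomputes the n×n×6 pairwise
attribute-similarity tensor once (with phrase- and word-pair caching —
attribute texts repeat heavily in registry data) and every pass reduces
to dot products against it.

## Recommendation and evaluation

A query is scored against each stored class by its mean overall
similarity to the class's stored members (mirroring `s_avg`; a
maximum-over-members aggregate is available behind a flag for
sensitivity analysis). If the query is itself among the members it is
excluded. Classes are ranked by score, ties broken by class name, and
truncated to k (default 10, the list length practical for expert
review).

Evaluation reports the **top-n match rate**: the percentage of labeled
queries whose true class appears within the top n candidates
(non-decreasing in n by construction). The harness also provides a
parameter-grid sweep over training ratio × threshold × per-class cap ×
n — where the per-class cap subsamples each class's stored training
members with the split seed, bounding both training cost and
recommendation evidence — and the DEC-concept overlap statistic (the
percentage of distinct test-set concept identifiers that also occur in
the training set), the standard way to grade how semantically similar a
testing set is to the training data. Percentages are reported to two
decimals. In the grid sweep the class-size filter is applied to the
training side after splitting; the `train` CLI command filters before
splitting so the verification report covers the same classes.

## Corpus handling

The canonical interchange is a flat CSV/JSON schema (one row per CDE:
`public_id`, the six attributes, semicolon-joined `dec_concepts`,
`mapped_class`); reading and writing round-trips exactly, with
`dec_concepts` serialized in sorted order so re-serialization is
byte-identical. A best-effort reader for caDSR CDE Browser XML exports
matches element names case-insensitively and skips (and counts)
unparseable records. Classes with fewer than `min_class_size` members
(default 10) are excluded before training — smaller classes provide too
few examples and act as noise. Splitting into training/verification
corpora is seeded and stratified per class by default (each class keeps
at least one member on each side; a non-stratified mode exists for
fidelity experiments). Records without a class label are legitimate
recommendation queries but are rejected by training.

## The synthetic-corpus generator

The generator emulates what makes registry CDE families learnable: each
class owns a content vocabulary, a record's object class (2 words),
property (1) and representation term (2) are drawn from it, the long
name is their concatenation, the value domain long name extends the
representation term, and the question text is the sentence frame
"what was the *property* of the *object class*". Content words are
pronounceable CV-syllable strings (length 4–10) from a synthetic
lexicon, so edit-distance collisions across classes are controlled
rather than accidental; the drawn content words double as the record's
DEC concept identifiers, giving the concept-overlap statistic an exact
expected value. Two dials set difficulty:

* `overlap_fraction` — the share of each class vocabulary drawn from a
  pool common to all classes (0 = disjoint classes, 1 = identical);
* `typo_rate` — per-word probability of one random single-character
  edit.

Defaults (19 classes × 60 members, 12 words per class vocabulary,
overlap 0.3, typo rate 0.05) mirror the scale of a realistically curated
training set of ~1100 records over 19 classes with moderate sharing.

`informative_attribute = i` switches to a parameter-recovery layout:
all six attributes carry exactly two words and no constant tokens
(equal word counts matter — a longer phrase or a shared sentence frame
hands an attribute a higher matched-word baseline and masks the
signal); attribute *i* draws from a tight per-class signature of at
most four words, while the other five carry striped "convention"
phrases from the common pool — deterministic phrasing that recurs at
the same member position *across* classes, the way representation-term
conventions recur across real registries. The stripes make between-class
similarity systematically exceed within-class similarity on the
non-informative attributes, so updates fire broadly while attribute *i*
holds the dominant within-class mean — the configuration in which this
learning rule provably concentrates weight on the informative attribute
(verified for every *i* over multiple seeds).

What the generator does **not** emulate: real NCI Thesaurus concept
codes or BRIDG class names, English morphology and synonymy,
heterogeneous class sizes within one corpus (configurable but not
defaulted), and curation artifacts such as retired records. Passing
tests on synthetic corpora therefore demonstrate the pipeline's
mechanics — separability, weight recovery, rate monotonicity,
reproducibility — not the match rates achievable on real registry
exports, which the harness can ingest via the canonical CSV/JSON or the
XML reader.

## Problem sizes and numerics

The test and acceptance workloads use corpora of 36–228 records
(up to 19 classes × 12 members) and 5–10 seeds per stochastic check;
the pairwise-tensor precomputation makes training on such corpora a
matter of seconds, and the generator defaults (~1140 records) remain
practical for CLI use. All randomness flows through seeded NumPy
generators; identical seeds and configs give byte-identical corpora and
model files. Weights are validated to the simplex at 1e−9 both after
every update and when loading a persisted model. Degenerate inputs
(single-member classes, a corpus with one class, concept-free test
sets, two empty words) raise typed errors rather than returning
conventional values, except where a convention is stated above (empty
attribute text).

## Known limitations

* The greedy matrix reduction is order-dependent under ties and is not
  an optimal assignment; it is used deliberately, as specified, rather
  than the Hungarian algorithm.
* The subset-inflation effect (short phrases match supersets perfectly)
  can over-score terse long names.
* The learning rule only updates on anchors whose own class fails to
  dominate; on cleanly separated corpora it leaves weights uniform by
  design.
* `edit_distance` on words longer than 256 distinct characters'
  alphabets is limited by edlib's alphabet bound — irrelevant for
  natural-language words.
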