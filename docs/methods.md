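# Methods

`dictmap` maps data elements across two data dictionaries. This note
records the model and procedure, the parameters that matter, what the
synthetic benchmark does and does not show, and the numerical and
design choices that were genuinely open.

## Problem and pipeline

Each dictionary row describes one *data element*: a name, an enclosing
table, short and long free-text descriptions, and a value specification
(an enumeration of codes, a numeric min–max range, or free text). The
task is to propose, for every element of a *query source*, a small
ranked window (default 5) of candidate matches from a *target source*,
or to flag the element as unmappable.

The pipeline is: **extract** (parse dictionaries into a metadata store,
infer value constraints) → **filter** (constraint blocking) → **score**
(description-text similarity) → **classify** (feature-based match
scoring, optional) → **suggest** (ranked windows).

### Constraint inference

Value specifications are classified by a deterministic, total grammar:
two numerics joined by `-`, `–` or `to` are a range; comma/semicolon
lists (optionally `code=label`) are coded, with cardinality = number of
distinct codes; `text`/`string`/… is free text; everything else —
including an inverted range — falls back to *unknown* with a warning.
Unknown never blocks anything downstream, so a misread specification
degrades evidence, not correctness.

### Blocking

Two hard constraint kinds block a pair when irreconcilable: coded vs.
range always; coded vs. coded when cardinalities differ by more than
`cardinality_tolerance` (default ±1 — sentinel codes like `8 = N/A`
come and go between datasets); range vs. range when disjoint. A side
with no hard constraint never blocks. Blocking is symmetric and
monotone in the tolerances, and can be disabled (`--no-blocking`) to
measure its contribution.

### Text similarity

Descriptions (short + long, concatenated) are tokenized by lowercasing,
splitting on non-alphanumerics, and removing a standard English
stopword list; no stemming by default (a flag enables a minimal
plural-stripping rule — element descriptions are short and aggressive
stemming conflates clinically distinct terms). Two scores are computed
over the joint corpus of both sources:

* **TF-IDF cosine** — smoothed idf, l2-normalized vectors (the
  scikit-learn formulation);
* **topic cosine** — cosine of per-document topic distributions from a
  batch-fit LDA with `topic_count` topics (default 20, seeded; there is
  no principled topic count for corpora of short descriptions, so it is
  configuration, fixed before use).

Elements with empty descriptions score 0 on both (they can still match
via names or constraints). Ordinal ranks (1 = best) are assigned per
query over the **post-blocking** candidate set — blocking changes rank
values, and ranks are meant to reflect what a user would actually be
shown. Ties break by (score desc, target name asc, target table asc)
everywhere, so every ranking in the package is reproducible.

A token-level Levenshtein distance over the *unfiltered* token
sequences (stopwords kept) complements the bag-of-words scores with
word-order information.

### Name matching

Element names are segmented into components: split on delimiters and
camel-case boundaries, then residual runs are greedily matched
longest-first against a vocabulary (built from all observed name
components plus the synonym list). Components are aligned greedily by
best pairwise similarity — exact or synonym = 1, otherwise normalized
character edit similarity — and the score is the aligned sum divided by
the larger component count, so unaligned components penalize. The score
is *not applicable* when either name is a single opaque run shorter
than 4 characters and unknown to the vocabulary or synonym map (a name
like `Q7X` carries no lexical signal); the threshold is configuration,
not an inference about any particular dataset. A starter
medical-abbreviation synonym list ships as an editable two-column text
resource; an empty map is legal. The scorer is deliberately rule-based
behind a pluggable interface — a learned scorer can be substituted, but
shipping one would require invented training data.

### Features and classification

Each candidate pair yields a fixed, documented 14-feature vector
(`dictmap.features.FEATURE_NAMES`): tfidf/topic scores and ranks, edit
distance, name applicability and score, source/target cardinality and
range bounds (NaN when not applicable; imputed to −1 inside the
classifier pipeline, since none of the suite's estimators represent
missingness natively), and the table-correspondence score.

**TCS.** For source table *S* and target table *T*,
`TCS(S,T) = |{e ∈ S : best_match(e) ∈ T}| / min(|S|,|T|)`, where
`best_match` is the *heuristic* rank-1 assignment (blocking +
description similarity) — never the truth labels, so the feature leaks
nothing. A literal per-pair variant (binary numerator over min table
size) is available for comparison (`per_pair_table_score`) but the
per-table proportion is what the feature is meant to capture. Empty
tables are an error.

**Classifier suite.** SMO-style SVM (`smo`, the default — an RBF SVC at
library defaults, scores via a logistic link on the decision value),
linear-margin SVM, logistic regression, random forest, CART decision
tree, and a small MLP. All hyperparameters are library defaults;
choosing per-dataset hyperparameters is out of scope. Session-derived
training sets are negative-heavy, and the unweighted margin this
induces acts as a deliberately conservative match boundary — the
emission rule below leans on precision while the shortlist ranking
protects recall. (A balanced-class-weight variant was tried during
design and rejected: upweighting 30 positives ~10× produced an overly
permissive boundary.)

**Scoring at scale.** Similarity and rank matrices are computed
vectorised over the full post-blocking cross product; the per-pair
Python feature extraction (edit distance, name alignment) is restricted
to a per-query *shortlist* of the top-`shortlist` (default 20) targets
by TF-IDF similarity — the classifier re-ranks a generous candidate
slate rather than the full cross product, keeping feature extraction
linear in the number of queries; a true match that description
similarity ranks below the shortlist is lost, which the limitations
section notes.

**Emission rule.** A query's window is emitted only when its top score
clears a threshold — 0.5 for both paths (the classifier's decision
boundary; mid-cosine for the heuristic path). This is the package's
mappability rule: within-window precision is taken over emitted
queries, and most queries of a real pair have no counterpart, so a
system that suggests for everything is worthless no matter how well it
ranks. 0.5 is the natural boundary of both score scales, fixed by that
semantics.

### Active learning and effort

Training labels come from a session loop: the system serves a query and
its ranked window; the user approves a match, asks for more, skips, or
ends. Approvals are positive labels; suggestions the user examined
without approving (the red-marked ones) are negative labels.
`build_training_set` tops negatives up to `negative_ratio` (default
3:1) per positive by seeded uniform sampling from the query's unblocked
targets — class balance must be controlled explicitly because sessions
produce variable rejection counts.

Two user strategies are modelled. *Strategy 1*: page through more
suggestions (a page = the window size, configurable) until the match
appears, giving up after `max_pages` (default 10) pages. *Strategy 2*:
skip unless the match is in the first window; a skip costs the
suggestions actually shown. Effort is elements examined: approved
queries cost the rank of the approved match, `E = Σ r(eᵢ)`. The passive
baseline is `K·N/4`: on average a person scans a quarter of the target
source per mapping found.

Query selection: before any model exists, queries are served
round-robin over the query source's tables — this samples a
representative mix of easy, hard, and unmatchable queries, so the
early rejections include informative near-miss negatives (confidence
order, serving the easiest first, is available but yields only trivial
labels). `run_active_session` puts the model in the loop: after every
`retrain_every` (default 5) approvals the classifier is refit on all
labels so far and the remaining queries are re-ordered by uncertainty —
smallest |top score − 0.5| first — so subsequent labels fall where the
model is least sure. Other selection policies (committee,
expected-model-change) fit behind the same interface but are not
implemented.

## Synthetic benchmark

Real clinical dictionaries are rarely redistributable, so all
evaluation runs on generated pairs. Each *concept* has a unique
(topic, attribute) core drawn from a bank of cognitive/clinical
assessment vocabulary (memory, bills, gait, blood pressure …  ×
score, severity, onset …) plus a qualifier and three concept-specific
filler words; both copies derive from the same concept sentence. Two
elements differing only in a qualifier would be the same measurement,
hence uniqueness is enforced on the core. The target-side copy is
perturbed: per-token synonym substitution with probability
`paraphrase_rate`, per-token dropout with `dropout_rate`, element-name
divergence per `rename_style` (abbreviation, delimiter change, synonym,
or a mix), and constraint perturbation with probability
`constraint_noise` (cardinality ±1, range shift ≤25% of width — within
the default blocking tolerance, mirroring the sentinel-code churn real
pairs show). Concepts land in corresponding tables (`form_i` ↔
`section_i`) unless shuffled with probability `table_shuffle`.

Defaults are the benchmark conditions: 200 shared concepts, 800
distractors per source (1000 elements per side), paraphrase 0.3,
dropout 0.1, constraint noise 0.05, 10 tables, shuffle 0.1, mixed
renames. The distractors draw on the same vocabulary distribution, so
the task is not trivially separable.

What passing the benchmark shows: the feature set and loop recover
high-precision, high-recall windows under paraphrase-style wording
divergence and mild constraint churn, at an order of magnitude less
labeling effort than brute-force reading. What it does not show:
robustness to real dictionaries' pathologies — boilerplate shared
across all descriptions, abbreviation-dense or empty descriptions,
many-to-one mappings, OCR noise — none of which the generator attempts
to mimic.

## Numerical choices and degenerate inputs

* Every stochastic step (generator, LDA, negative sampling, estimator
  seeds) is driven by explicit integer seeds; fixed seeds reproduce
  stores, topic distributions, training sets and reports bit-for-bit.
* Tie-breaks are total orders everywhere (documented above), so ranks
  and reports are order-independent and regeneration is byte-identical.
* Cosines are clamped to [0, 1] against floating-point drift.
* Empty candidate sets, all-blocked queries, empty descriptions, and
  single-class training sets all have defined behaviour (empty window /
  unmappable flag / zero scores / explicit error, respectively).
* Information gain (feature diagnostics) discretizes continuous
  features into ≤10 equal-width bins with NaN as its own bin; entropies
  in bits.

## Known limitations

* One-to-one suggestion windows per query; no global assignment is
  enforced (an optional greedy post-pass would be a small addition, but
  per-query windows match how analysts actually vet mappings).
* The name matcher's applicability rule and the component vocabulary
  are heuristics; dictionaries whose names are all opaque codes get no
  name signal.
* The shortlist cap (20) bounds how far the classifier can promote a
  candidate that description similarity ranked very low.
* Effort modelling assumes a perfect oracle user; real users mislabel.
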