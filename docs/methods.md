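# Methods

This document describes the model implemented by `eventex`, the meaning
and default value of every tunable parameter, the scope of the synthetic
corpus generator, and the known limitations of the package.

## 1. Data model

### Standoff documents

A document (`eventex.standoff.Document`) couples the raw text (`.txt`),
given entity annotations (`.a1`), event/relation/modality annotations
(`.a2`) and a CoNLL-style dependency parse (`.conll`, six columns:
index, form, stem, POS, head, relation; head 0 is the root). Offsets are
0-based, half-open, in characters. One non-empty line of the `.txt`
file is one sentence; parse blocks align with sentences in order. When
the parse gives `_` for a stem, the bundled Porter (1980) stemmer fills
it in. Multi-token protein names whose boundaries fall strictly inside a
parse token can be re-tokenized with `split_protein_name_tokens`; the
fragment containing the original head character inherits the token's
dependencies.

### The event graph

Annotations are converted to a per-sentence semantic graph
(`eventex.graph.EventGraph`): nodes are entities (given, from `.a1`) and
event triggers (from `.a2`), edges are role-labelled arguments
(`Theme`, `Cause`, `Site`, …; numeric suffixes as in `Theme2` are part
of the surface form but stripped to the base role for classification).
Each node is anchored to a **head token**: the root of the dependency
subtree inside the node's span, with ties broken toward the *rightmost*
candidate (biomedical noun phrases are predominantly head-final); if no
span token exists, the nearest token is used.

Two derived views are central:

* **Merged graph** (`to_merged_graph`): one node per (head token, type),
  with all argument edges of the pooled events attached. Edge detection
  is trained on this view, so several gold events sharing a trigger do
  not produce contradictory training labels.
* **Resolved graph** (`resolve_equivalences`): `Equiv` statements are
  expanded by recursive cross-product duplication — an event with k
  arguments in equivalence classes of sizes n1…nk yields
  n1·…·nk events — with signature-based deduplication. Resolution is
  enabled by default wherever a gold standard is prepared, since
  shared-task gold is resolved the same way.

Task **schemas** (bundled JSON: `ge`, `epi`, `id`, `bb`, `bi`, `rel`,
`ren`) declare entity and event types, supertypes, per-role valency
(min/max counts), relation types and undirectedness, zero-argument event
types, and the site-argument mode:

* *protein-linked* (default, used by `ge`): site entities attach to the
  protein they belong to; site edges are excluded from event-level edge
  classification and re-paired with events on output
  (`pair_sites_on_output`). When several events of a protein are
  compatible with a site, the site is attached to **all** of them — the
  annotation gives no basis for choosing, and attaching to all is the
  recall-preserving resolution.
* *trigger-linked* (used by `epi`): site edges emanate from the trigger
  and are classified like any other role.

## 2. The staged pipeline

All stages use sparse binary/real features hashed through a
`FeatureIndex` (dense ids from 1; frozen at training time, unseen
features dropped and counted at prediction time) and one-vs-rest linear
SVMs (scikit-learn `LinearSVC`, dual=False) behind a thin
`ModelBundle` wrapper. The negative class is the reserved label `neg`.

### Stage 1 — trigger detection

Every token not covered by a given entity is an example; the label is
the class of the trigger(s) headed at that token, or `neg`. Tokens
heading triggers of several types get a **merged class**: the component
type names, deduplicated, sorted, joined with `---` (a separator that
cannot occur in type names). After classification, merged predictions
are split back into one node per component type.

Features: token surface/lowercase/stem/POS, padded character 2- and
3-grams (emitted only when the raw token is at least as long as the
n-gram order), punctuation/digit indicators, bag-of-words and
entity-count sentence features, dependency-chain features up to depth 3
(undirected walks, each step tagged governor/dependent, terminal token
attributes in {text, POS, stem} variants — the three attributes that are
always available from the parse), and optional external-lexicon
features.

### Recall adjustment

The score of `neg` is multiplied by β before the argmax, *only when*
`neg` has the highest raw score; a flip occurs iff the adjusted negative
score is strictly below some positive class score. Hence β = 1 is the
identity and decreasing β monotonically (weakly) decreases the number of
negative decisions — both properties are enforced by tests. β is chosen
on the development set by end-to-end event F-score, ties resolved toward
β closest to 1, then smaller. Default grid: 0.5–1.2 in steps of 0.1 — a
symmetric window around the neutral value 1.0 wide enough to visibly
move the precision/recall balance; values above 1 allow the tuner to
*raise* precision if the trigger model over-fires.

### Stage 2 — edge detection

Examples are directed (trigger, target) node pairs permitted by the
schema (undirected unordered pairs for relation-only tasks); labels are
base role names or `neg`. Gold labels come from the **merged** gold
graph. Features: both terminal tokens' features, node type/supertype
features, dependency shortest-path N-grams (n ≤ 3) built with
networkx `all_shortest_paths` (the lexicographically smallest path on
ties, so features are deterministic), with token-trigram and
dependency-trigram variants emitted in both orientations and
direction-tagged bigrams, plus path-length and no-path indicators.

### Stage 3 — unmerging

For each predicted trigger node, argument subsets of its outgoing core
edges satisfying the schema valency are enumerated (the empty subset
only for declared zero-argument types). A binary SVM labels each subset
`event`/`neg`; gold labels are multiset matches against the gold events
merged at that node. Assembly is recursive over nested event arguments
with a cycle guard.

Caps: at most **64 candidates per node** and **10 outgoing edges per
node**. Exhaustive enumeration is exponential in the edge count; these
caps keep the worst case bounded while being far above anything
produced by realistic sentences (shared-task events rarely exceed 4
arguments). When the cap binds, lowest-confidence edges are pruned
first and a warning is emitted.

### Stage 4 — rule validation

A fixed-point cascade deletes events violating the schema (missing
mandatory roles, wrong target types), then events referencing deleted
events, then signature duplicates, until stable.

### Stage 5 — modality

Independent binary SVMs for Negation and Speculation over trigger-token
and sentence features (including a speculation-word lexicon hook).

### Rule systems

* **Reverse types** (`epi_reverse_rule`): a forward type is flipped to
  its reverse (e.g. `Methylation` → `Demethylation`) when the trigger
  text starts with `de` (case-insensitive, **prefix only** — substring
  matching would fire on words like *hidden*) or contains `remov`,
  `loss` or `erasure`. Seven forward types participate
  (`EPI_REVERSE_TYPES`).
* **Bacterium span extension** (`bb_extend_span`): from a detected head
  token, the span grows in both directions while neighbours are accepted
  by a lexicon, ~20 Latinate suffix rules (`-us`, `-um`, `-ii`, …), 16
  substring rules, or the single-capital-plus-dot genus abbreviation
  pattern (`B.`).

## 3. Training protocol

* **C selection**: each stage's C is chosen in isolation on the
  development set by the stage's own classification F-score (micro-F
  over positive classes), ties toward smaller C (prefer the stronger
  regularizer); the model is then retrained on train+development.
  Fine grid `DEFAULT_C_GRID` = 2⁻⁸ … 2⁶ (powers of 2); the pipeline's
  default is the coarse subset `PIPELINE_C_GRID` =
  (0.0625, 0.25, 1.0, 4.0, 16.0), a runtime/accuracy compromise —
  stage F on the synthetic corpora is flat across neighbouring powers
  of 2, so the coarse grid loses nothing measurable while training 3×
  faster. Pass `c_grid=` to override.
* **β selection**: after stage training, β is tuned against end-to-end
  development event F (see above), then all stages are refitted on the
  combined data.

## 4. Evaluation

`match_events` implements **approximate-span, approximate-recursive**
matching: a predicted trigger matches a gold trigger if their spans
overlap after the gold span is extended by ±1 token (the extension
window absorbs off-by-one tokenization differences without allowing
matches across phrase boundaries); entity arguments must match exactly
by span or be in the same equivalence class; event arguments are matched
recursively with backtracking to find a consistent bijection; matching
between the predicted and gold sets is greedy one-to-one over a
deterministic ordering. P/R/F use the convention 0/0 = 0.

> **Important:** this evaluator is the package's own implementation of
> approximate span/recursive matching. It is an **approximation of the
> official shared-task scoring services**, not a reimplementation of
> them; absolute scores on real task data may differ from official
> numbers, and the official services should be used for any formal
> comparison.

Cross-sentence gold events are *kept* in the evaluation reference even
though the sentence-level extractor cannot produce them, so reported
recall is honest about this structural limitation.

## 5. Self-training utilities

Predicted events carry SVM confidences. `normalize_confidences`
standardizes them to zero mean / unit variance **per group**, where a
group is (event type, number of entity arguments, number of event
arguments) — raw margins are not comparable across classifier
sub-problems. Sample standard deviation (ddof=1) is used; groups of
size 1 or zero variance get z = 0. `select_band` keeps events with z in
the half-open interval [lo, hi); `select_even_distribution` additionally
caps each group's count, sampling uniformly, and closes the selection
under nested event references (closure additions are flagged).

## 6. Learning curves

`learning_curve` evaluates the pipeline on nested training subsets: one
shuffle of the document list, subsets are prefixes, so every smaller
subset is contained in every larger one and curve differences reflect
data volume only. Subset size is `round(n · fraction/100)` with
round-half-up, minimum 1 document.

## 7. The synthetic corpus generator

`eventex.synthetic.generate` produces deterministic, fully annotated
corpora (text, `.a1`, `.a2`, CoNLL parses) from template sentences with
hand-written rule parses: passive simple events (Gene_expression,
Phosphorylation), Binding with two Themes, Regulation with Cause,
nested regulation-of-phosphorylation, merged-trigger sentences
("induces"/"triggers" heading two event types at one token),
apposition-based `Equiv` aliases, cross-sentence event pairs, and
eventless noise sentences. Default rates (`CorpusSpec`): 5% noise,
35% nesting, 7% equivalence, 5% intersentence, 2% merged triggers,
7% negation, 6% speculation; splits 500/100/100 documents; generation
is reproducible from a single seed (per-split derived seeds), and
corpus statistics (event counts, phenomenon percentages) are computed
alongside.

**What the generator emulates:** the structural dimensions of
shared-task corpora — standoff format, nested and merged events,
equivalence, modality, cross-sentence annotations, trigger ambiguity
under noise — at controllable rates, with parses that are correct by
construction.

**What it does not emulate:** real biomedical language. Vocabulary is a
40-symbol invented protein pool and a small trigger lexicon; syntax is
templatic; parses contain no errors. Consequently, tests passing on
synthetic data demonstrate that the *machinery* is correct (formats,
graph transforms, learning plumbing, parameter selection, evaluation)
and that the pipeline can recover planted structure from honest signal
— they do **not** demonstrate state-of-the-art accuracy on real
corpora, which depends on feature engineering against real parser
errors and lexical variety.

Problem sizes used in the test suite and acceptance script (500/100
documents, 500-graph oracle comparisons, 10,000 score vectors) are the
package's own choices, balancing statistical resolution against a
few-minute runtime on one core.

## 8. Known limitations

* The evaluator approximates, and is not a substitute for, the official
  shared-task scorers (Section 4).
* Extraction is sentence-level; cross-sentence events are never
  produced (they are still counted in evaluation).
* The pipeline is greedy-staged: trigger errors propagate; there is no
  joint inference or beam over stages.
* `LinearSVC` margins are used directly as confidences; they are not
  calibrated probabilities (hence the per-group standardization for
  self-training).
* The Porter stemmer and the rule lexicons are English-specific.
* Recall-adjustment tie handling (negative wins exact score ties)
  and the candidate caps (64 subsets / 10 edges per node) are fixed
  policy choices; the caps warn when they bind.
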