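# eventex

A staged machine-learning pipeline for biomedical **event extraction**:
turning sentences such as *"NF-kappaB regulates the phosphorylation of
STAT3"* into structured, typed, possibly nested event records
(`Regulation(Cause: NF-kappaB, Theme: Phosphorylation(Theme: STAT3))`).
The package reads and writes the standoff annotation format used by the
BioNLP shared tasks (`.txt` / `.a1` / `.a2` files plus CoNLL-style
dependency parses), represents annotations as a semantic graph of trigger
and entity nodes connected by role-labelled edges, and extracts events
with a sequence of linear support-vector classifiers.

It is aimed at researchers in biomedical natural-language processing who
want a compact, fully tested reference implementation of the classic
staged approach — trigger detection, argument-edge detection, SVM-based
unmerging, rule validation and modality detection — together with a
deterministic synthetic-corpus generator that makes every part of the
system testable without any external data.

## The model

Extraction is decomposed into consecutive classification stages, each a
multiclass one-vs-rest linear SVM over sparse lexical and dependency-path
features:

1. **Trigger detection.** Every token is classified into an event type or
   the negative class. Tokens that denote several events of different
   types receive a *merged* class (the component names joined with
   `---`), which is split back into separate nodes after prediction.
   Precision/recall is tuned by multiplying the negative class score by
   β ≤ 1 before taking the argmax ("recall adjustment"); β is chosen to
   maximize end-to-end event F-score on the development set.
2. **Edge detection.** Every directed trigger→(trigger|entity) pair
   allowed by the task schema is classified into a role label (`Theme`,
   `Cause`, `Site`, …) or the negative class, producing a *merged* event
   graph with one node per (token, type).
3. **Unmerging.** Each trigger node's outgoing edges are enumerated into
   argument subsets that satisfy the schema's valency constraints; a
   binary SVM decides which subsets become actual events, and nested
   events are assembled recursively.
4. **Rule validation.** A fixed-point cascade removes structurally
   invalid events (and any events that referenced them) and duplicates.
5. **Modality detection.** Independent binary SVMs mark events as
   negated or speculated.

Task schemas for seven task configurations (`ge`, `epi`, `id`, `bb`,
`bi`, `rel`, `ren`) are bundled as JSON and drive candidate generation,
valency filtering and role inventories. Two rule systems are included:
reverse-type mapping for epigenetics tasks (e.g. *demethylation* →
reverse of *Methylation*) and dictionary/suffix-based bacterium-name span
extension. Supporting components cover equivalence (`Equiv`) resolution
by recursive cross-product duplication, approximate-span/recursive event
matching for evaluation, confidence standardization and band selection
for self-training, and nested-subset learning curves.

## Worked example

All numbers below are actual output of the commands shown. Generate a
small synthetic corpus, train, predict and evaluate:

```bash
$ eventex --seed 7 generate corpus --n-train 60 --n-devel 20 --n-test 10
$ eventex train corpus/train corpus/devel --model-out model.pkl
{
  "trigger": {
    "C": 0.25,
    "devel_f": 1.0,
    "n_train": 942,
    "n_devel": 363,
    "n_features": 2265
  },
  "edge": {
    "C": 0.25,
    "devel_f": 0.9823677581863981,
    ...
  },
  ...
  "recall_adjustment": {
    "beta": 1.0,
    "devel_event_f": 0.962121212121212
  }
}
$ eventex predict corpus/test --model model.pkl --out preds
wrote 10 .a2 files to preds
$ eventex evaluate corpus/test preds
class                       TP    FP    FN       P       R       F
Binding                      8     0     0  1.0000  1.0000  1.0000
Gene_expression             17     0     0  1.0000  1.0000  1.0000
Negative_regulation          4     0     0  1.0000  1.0000  1.0000
Phosphorylation              9     1     0  0.9000  1.0000  0.9474
Positive_regulation          7     0     0  1.0000  1.0000  1.0000
Regulation                   6     0     0  1.0000  1.0000  1.0000
TOTAL                       51     1     0  0.9808  1.0000  0.9903
```

A predicted `.a2` file looks like:

```
T17	Binding 6 11	binds
T19	Regulation 75 83	controls
T20	Phosphorylation 88 103	phosphorylation
E1	Binding:T17 Theme:T1 Theme2:T2
E3	Phosphorylation:T20 Theme:T6
E4	Regulation:T19 Cause:T5 Theme:E3
```

The same workflow is available from Python via
`eventex.pipeline.run_pipeline`; on the default 500/100-document study
corpus it reports (seed 1):

```python
>>> from eventex.pipeline import run_pipeline
>>> run_pipeline(train_docs, devel_docs, schema)["devel"]
{'precision': 0.9863, 'recall': 0.9813, 'f': 0.9838, 'tp': 576, 'fp': 8, 'fn': 11}
```

Recall is bounded below 100% by design: documents may contain
cross-sentence events that the sentence-level extractor cannot recover,
and these remain in the evaluation gold standard.

## Documentation

See `docs/methods.md` for the full description of the graph
representation, the staged procedure, every tunable parameter and its
default, the scope of the synthetic-corpus generator, and known
limitations (in particular, the bundled evaluator is an approximation of
the official shared-task scorers).
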