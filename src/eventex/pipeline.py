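"""End-to-end pipeline orchestration.

Stages run in order: trigger detection, recall adjustment, edge detection,
unmerging, validation, modality detection, standoff output. Each stage's
regularization parameter is selected in isolation on the development set
(maximizing that stage's own classification F-score); the recall-adjustment
multiplier is tuned against event-level F of the whole pipeline; final
models are retrained on the combined training and development data. Tasks
whose entities are all given skip trigger detection and start from edge
detection.

Also here: document-granular learning curves and confidence-stratified
self-training selection (per-group score normalization, half-open
confidence bands, even-distribution sampling with nested-event closure).
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from eventex.evaluation import MatchCounts, match_events, prf
from eventex.features import FeatureIndex, Lexicons, SparseExample
from eventex.graph import (
    ArgumentEdge,
    EntityNode,
    Event,
    EventGraph,
    build_graph,
    pair_sites_on_output,
    resolve_equivalences,
    select_head_token,
    to_merged_graph,
)
from eventex.learning import (
    DEFAULT_BETA_GRID,
    NEGATIVE,
    ModelBundle,
    classification_f1,
    optimize_C,
    optimize_recall_multiplier,
    retrain_combined,
    train,
)
from eventex.schema import TaskSchema
from eventex.stages import (
    generate_edge_examples,
    generate_modality_examples,
    generate_trigger_examples,
    split_class_label,
    split_merged_predictions,
)
from eventex.standoff import Document, write_a2
from eventex.unmerging import (
    EventCandidate,
    assemble_events,
    candidate_features,
    enumerate_candidates,
    generate_unmerge_examples,
    validate_events,
)

log = logging.getLogger("eventex")

# a coarse sweep for end-to-end runs; stages are individually insensitive
# past this resolution and the full power-of-two grid is available in config
PIPELINE_C_GRID: tuple[float, ...] = (0.0625, 0.25, 1.0, 4.0, 16.0)


@dataclass
class PipelineConfig:
    c_grid: tuple[float, ...] = PIPELINE_C_GRID
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID
    beta_unmerge: float = 1.0
    extension_tokens: int = 1
    resolve_equiv: Optional[bool] = None   # None = follow the schema
    seed: int = 0


@dataclass
class DocData:
    doc: Document
    gold_graphs: list[EventGraph]          # resolved (training view)
    merged_graphs: list[EventGraph]        # merged gold (edge/unmerge view)
    eval_events: list[Event]               # full annotated gold (evaluation)
    given_nodes: list[list[EntityNode]]    # per sentence
    equiv_spans: list[list[tuple[int, int]]]


def _equiv_spans(doc: Document) -> list[list[tuple[int, int]]]:
    ents = doc.entities()
    out = []
    for members in doc.equiv_sets():
        spans = [tuple(ents[m].spans[0]) for m in members if m in ents]
        if len(spans) >= 2:
            out.append(spans)
    return out


def prepare_documents(docs: Sequence[Document], schema: TaskSchema,
                      resolve: Optional[bool] = None) -> list[DocData]:
    do_resolve = schema.resolve_equiv if resolve is None else resolve
    out = []
    for doc in docs:
        # full annotated gold (intersentence events included) for evaluation
        full_graphs, _ = build_graph(doc, schema, drop_intersentence=False)
        eval_events = [ev for g in full_graphs for ev in g.events]
        graphs, _ = build_graph(doc, schema)
        if do_resolve:
            resolve_equivalences(graphs, doc.equiv_sets(), schema)
        merged = to_merged_graph(graphs, schema)
        given = [[n for n in g.nodes.values() if n.given]
                 for g in graphs]
        out.append(DocData(doc=doc, gold_graphs=graphs, merged_graphs=merged,
                           eval_events=eval_events, given_nodes=given,
                           equiv_spans=_equiv_spans(doc)))
    return out


@dataclass
class TrainedPipeline:
    schema: TaskSchema
    config: PipelineConfig
    lexicons: Optional[Lexicons]
    trigger_model: Optional[ModelBundle] = None
    edge_model: Optional[ModelBundle] = None
    unmerge_model: Optional[ModelBundle] = None
    modality_models: dict[str, ModelBundle] = field(default_factory=dict)
    beta: float = 1.0
    stage_info: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# example generation over prepared corpora

def _trigger_examples(data: Sequence[DocData], lexicons) -> list[SparseExample]:
    out = []
    for d in data:
        for sent, graph, given in zip(d.doc.sentences, d.gold_graphs,
                                      d.given_nodes):
            out.extend(generate_trigger_examples(sent, d.doc.doc_id, graph,
                                                 given, lexicons))
    return out


def _edge_examples(data: Sequence[DocData], schema, lexicons):
    out = []
    for d in data:
        for sent, mg in zip(d.doc.sentences, d.merged_graphs):
            out.extend(generate_edge_examples(mg, sent, d.doc.doc_id, schema,
                                              lexicons, labeled=True))
    return out


def _unmerge_examples(data: Sequence[DocData], schema):
    out = []
    for d in data:
        for sent, mg in zip(d.doc.sentences, d.merged_graphs):
            out.extend(ex for _, ex in generate_unmerge_examples(
                mg, sent, d.doc.doc_id, schema, labeled=True))
    return out


def _modality_examples(data: Sequence[DocData], dim, lexicons):
    out = []
    for d in data:
        for sent, graph, given in zip(d.doc.sentences, d.gold_graphs,
                                      d.given_nodes):
            out.extend(generate_modality_examples(
                graph.events, sent, d.doc.doc_id, dim, given, lexicons,
                labeled=True))
    return out


def _build_index(example_sets: Sequence[Sequence[SparseExample]]) -> FeatureIndex:
    index = FeatureIndex()
    for examples in example_sets:
        for ex in examples:
            for name in ex.features:
                index.get(name)
    return index


# ---------------------------------------------------------------------------
# prediction

def predict_document(pipe: TrainedPipeline, doc: Document,
                     beta: Optional[float] = None) -> list[Event]:
    """Run the staged pipeline on one (parsed) document."""
    schema = pipe.schema
    beta = pipe.beta if beta is None else beta
    events_out: list[Event] = []
    given_per_sentence: list[list[EntityNode]] = []
    for sent in doc.sentences:
        given = []
        for ann in doc.annotations:
            if ann.kind != "entity" or ann.source != "a1":
                continue
            s0 = ann.spans[0][0]
            if sent.char_start <= s0 < sent.char_end:
                given.append(EntityNode(
                    node_id=ann.line_id, type=ann.type,
                    head_token=select_head_token(ann.spans[0], sent),
                    char_spans=list(ann.spans), given=True, text=ann.text,
                    sentence_index=sent.index))
        given_per_sentence.append(given)

    for sent, given in zip(doc.sentences, given_per_sentence):
        graph = EventGraph(sentence_index=sent.index)
        for n in given:
            graph.add_node(n)

        # trigger detection + recall adjustment
        if pipe.trigger_model is not None:
            examples = sorted(
                generate_trigger_examples(sent, doc.doc_id, None, given,
                                          pipe.lexicons),
                key=lambda e: e.example_id)
            if examples:
                X = pipe.trigger_model.feature_index.transform(examples)
                scores = pipe.trigger_model.decision_scores(X)
                labels = pipe.trigger_model.predict(X, beta=beta)
                preds = []
                for ex, label, row in zip(examples, labels, scores):
                    if label != NEGATIVE:
                        conf = float(np.max(row))
                        preds.append((sent, ex.provenance[2], label, conf))
                for node in split_merged_predictions(preds):
                    graph.add_node(node)

        # edge detection
        if pipe.edge_model is not None and len(graph.nodes) >= 2:
            examples = generate_edge_examples(graph, sent, doc.doc_id, schema,
                                              pipe.lexicons, labeled=False)
            if examples:
                ordered = sorted(examples, key=lambda e: e.example_id)
                X = pipe.edge_model.feature_index.transform(ordered)
                scores = pipe.edge_model.decision_scores(X)
                labels = pipe.edge_model.predict(X)
                for ex, label, row in zip(ordered, labels, scores):
                    if label == NEGATIVE:
                        continue
                    _, _, src, dst = ex.provenance
                    conf = float(np.max(row))
                    for comp in split_class_label(label):
                        directed = comp not in schema.undirected_relation_types
                        graph.edges.append(ArgumentEdge(
                            src, dst, comp, directed=directed,
                            confidence=conf))

        # unmerging
        accepted: list[EventCandidate] = []
        if schema.event_types:
            for node in sorted(graph.nodes.values(), key=lambda n: n.node_id):
                if node.given or node.type not in schema.event_types:
                    continue
                cands = enumerate_candidates(node, graph.outgoing(node.node_id),
                                             schema)
                if not cands:
                    continue
                if pipe.unmerge_model is None:
                    accepted.extend(cands)
                    continue
                exs = []
                for k, cand in enumerate(cands):
                    exs.append(SparseExample(
                        example_id=f"{doc.doc_id}.s{sent.index}.u."
                                   f"{node.node_id}.{k}",
                        features=candidate_features(cand, graph, sent, schema),
                        label=NEGATIVE))
                X = pipe.unmerge_model.feature_index.transform(exs)
                scores = pipe.unmerge_model.decision_scores(X)
                labels = pipe.unmerge_model.predict(
                    X, beta=pipe.config.beta_unmerge)
                for cand, label, row in zip(cands, labels, scores):
                    if label != NEGATIVE:
                        cand.confidence = float(np.max(row))
                        accepted.append(cand)
        events = assemble_events(graph, accepted, schema)
        events, _ = validate_events(events, schema)

        # site re-attachment (protein-linked mode)
        site_roles = {r for roles in schema.event_types.values()
                      for r, s in roles.items() if s.site}
        site_edges = [e for e in graph.edges
                      if e.type in site_roles
                      and e.source in graph.nodes
                      and graph.nodes[e.source].given]
        if site_edges:
            events, _ = pair_sites_on_output(events, site_edges, graph, schema)

        # modality
        for dim, model in pipe.modality_models.items():
            m_examples = generate_modality_examples(
                events, sent, doc.doc_id, dim, given, pipe.lexicons,
                labeled=False)
            if not m_examples:
                continue
            triggered = [ev for ev in events if ev.trigger is not None]
            X = model.feature_index.transform(m_examples)
            labels = model.predict(X)
            for ev, label in zip(triggered, labels):
                if label == dim:
                    if dim == "Negation":
                        ev.negation = True
                    else:
                        ev.speculation = True
        events_out.extend(events)
    return events_out


def predict_corpus(pipe: TrainedPipeline, docs: Sequence[Document],
                   beta: Optional[float] = None) -> dict[str, list[Event]]:
    return {doc.doc_id: predict_document(pipe, doc, beta) for doc in docs}


def evaluate_corpus(data: Sequence[DocData],
                    predictions: dict[str, list[Event]],
                    extension_tokens: int = 1) -> MatchCounts:
    total = MatchCounts()
    for d in data:
        counts = match_events(d.eval_events,
                              predictions.get(d.doc.doc_id, []),
                              doc=d.doc, equiv_spans=d.equiv_spans,
                              extension_tokens=extension_tokens)
        total.merge(counts)
    return total


# ---------------------------------------------------------------------------
# training

def train_pipeline(train_docs: Sequence[Document],
                   devel_docs: Sequence[Document],
                   schema: TaskSchema,
                   config: PipelineConfig | None = None,
                   lexicons: Optional[Lexicons] = None) -> TrainedPipeline:
    """Train all stages, select C per stage in isolation on the development
    set, tune the recall multiplier against end-to-end event F, and retrain
    every model on train+devel."""
    config = config or PipelineConfig()
    pipe = TrainedPipeline(schema=schema, config=config, lexicons=lexicons)
    train_data = prepare_documents(train_docs, schema, config.resolve_equiv)
    devel_data = prepare_documents(devel_docs, schema, config.resolve_equiv)
    info = pipe.stage_info

    def fit_stage(name, train_ex, devel_ex):
        if not train_ex or not any(e.label != NEGATIVE for e in train_ex):
            log.info("stage %s: no positive training examples, skipped", name)
            return None
        index = _build_index([train_ex, devel_ex])
        if devel_ex:
            best_c, best_f = optimize_C(train_ex, devel_ex, config.c_grid,
                                        feature_index=index)
        else:
            best_c, best_f = sorted(config.c_grid)[0], float("nan")
        info[name] = {"C": best_c, "devel_f": best_f,
                      "n_train": len(train_ex), "n_devel": len(devel_ex),
                      "n_features": len(index)}
        log.info("stage %s: C=%g devel-F=%.4f (%d train examples)",
                 name, best_c, best_f, len(train_ex))
        model = train(train_ex, best_c, index)
        return model

    # examples per stage, generated once and reused for the final refit
    stage_examples: dict[str, tuple[list, list]] = {}
    if schema.trigger_classes():
        stage_examples["trigger"] = (_trigger_examples(train_data, lexicons),
                                     _trigger_examples(devel_data, lexicons))
        pipe.trigger_model = fit_stage("trigger", *stage_examples["trigger"])
    else:
        log.info("all entities given: starting from edge detection")

    stage_examples["edge"] = (_edge_examples(train_data, schema, lexicons),
                              _edge_examples(devel_data, schema, lexicons))
    pipe.edge_model = fit_stage("edge", *stage_examples["edge"])
    if schema.event_types:
        stage_examples["unmerge"] = (_unmerge_examples(train_data, schema),
                                     _unmerge_examples(devel_data, schema))
        pipe.unmerge_model = fit_stage("unmerge", *stage_examples["unmerge"])
    for dim in schema.modality_types:
        stage_examples[f"modality-{dim}"] = (
            _modality_examples(train_data, dim, lexicons),
            _modality_examples(devel_data, dim, lexicons))
        model = fit_stage(f"modality-{dim}",
                          *stage_examples[f"modality-{dim}"])
        if model is not None:
            pipe.modality_models[dim] = model

    # freeze indexes before any prediction
    for model in [pipe.trigger_model, pipe.edge_model, pipe.unmerge_model,
                  *pipe.modality_models.values()]:
        if model is not None:
            model.feature_index.freeze()

    # recall-adjustment multiplier against end-to-end devel F
    if pipe.trigger_model is not None and devel_data:
        def metric(beta: float) -> float:
            preds = predict_corpus(pipe, [d.doc for d in devel_data], beta=beta)
            counts = evaluate_corpus(devel_data, preds,
                                     config.extension_tokens)
            return prf(counts)[2]
        beta, beta_f = optimize_recall_multiplier(metric, config.beta_grid)
        pipe.beta = beta
        info["recall_adjustment"] = {"beta": beta, "devel_event_f": beta_f}
        log.info("recall adjustment: beta=%.2f devel event F=%.4f",
                 beta, beta_f)

    # final models: retrain on train+devel at the chosen C
    def refit(name, model):
        if model is None or name not in stage_examples:
            return model
        train_ex, devel_ex = stage_examples[name]
        if not devel_ex:
            return model
        model.feature_index.frozen = False
        refitted = retrain_combined(train_ex, devel_ex, info[name]["C"],
                                    model.feature_index)
        refitted.feature_index.freeze()
        return refitted

    pipe.trigger_model = refit("trigger", pipe.trigger_model)
    pipe.edge_model = refit("edge", pipe.edge_model)
    pipe.unmerge_model = refit("unmerge", pipe.unmerge_model)
    for dim in list(pipe.modality_models):
        pipe.modality_models[dim] = refit(f"modality-{dim}",
                                          pipe.modality_models[dim])
    return pipe


def run_pipeline(train_docs, devel_docs, schema,
                 config: PipelineConfig | None = None,
                 lexicons: Optional[Lexicons] = None,
                 eval_docs=None) -> tuple[TrainedPipeline, dict]:
    """Train and evaluate; returns the pipeline and a result summary."""
    config = config or PipelineConfig()
    pipe = train_pipeline(train_docs, devel_docs, schema, config, lexicons)
    target_docs = list(eval_docs) if eval_docs is not None else list(devel_docs)
    data = prepare_documents(target_docs, schema, config.resolve_equiv)
    preds = predict_corpus(pipe, target_docs)
    counts = evaluate_corpus(data, preds, config.extension_tokens)
    p, r, f = prf(counts)
    summary = {"precision": p, "recall": r, "f": f,
               "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
               "stages": pipe.stage_info}
    return pipe, summary


def write_predictions(pipe: TrainedPipeline, docs: Sequence[Document],
                      outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        events = predict_document(pipe, doc)
        (outdir / f"{doc.doc_id}.a2").write_text(write_a2(events, doc),
                                                 encoding="utf-8")


# ---------------------------------------------------------------------------
# learning curves

def subset_size(n_docs: int, fraction: float) -> int:
    """Round half up, minimum one document."""
    k = int(math.floor(n_docs * fraction / 100.0 + 0.5))
    return max(1, k)


def learning_curve(train_docs: Sequence[Document],
                   devel_docs: Sequence[Document],
                   schema: TaskSchema,
                   fractions: Sequence[float] = (100, 64, 32, 16, 8, 4, 2),
                   seed: int = 0,
                   config: PipelineConfig | None = None,
                   lexicons: Optional[Lexicons] = None) -> list[dict]:
    """F-score against the fixed development set as a function of training
    corpus size. Reduction is document-granular and nested: the training
    set at each fraction is a subset of the set at every larger fraction
    (one shuffle, shared prefix)."""
    fractions = sorted(fractions, reverse=True)
    rng = random.Random(seed)
    shuffled = list(train_docs)
    rng.shuffle(shuffled)
    results = []
    for frac in fractions:
        k = subset_size(len(shuffled), frac)
        subset = shuffled[:k]
        _, summary = run_pipeline(subset, devel_docs, schema, config, lexicons)
        results.append({"fraction": frac, "n_documents": k,
                        "f": summary["f"], "precision": summary["precision"],
                        "recall": summary["recall"],
                        "doc_ids": [d.doc_id for d in subset]})
    return results


# ---------------------------------------------------------------------------
# self-training selection

@dataclass
class ScoredEvent:
    event: Event
    confidence: float
    doc_id: str = ""
    z: float = 0.0
    from_closure: bool = False

    @property
    def group_key(self) -> tuple[str, int, int]:
        n_ent = len(self.event.entity_args())
        n_ev = len(self.event.event_args())
        return (self.event.type, n_ent, n_ev)


def normalize_confidences(events: Sequence[ScoredEvent]) -> list[ScoredEvent]:
    """Standardize confidences to mean 0 / s.d. 1 separately within each
    group defined by (event type, number of entity arguments, number of
    recursive event arguments); sample (n-1) standard deviation. Singleton
    and zero-variance groups get z = 0."""
    groups: dict[tuple, list[ScoredEvent]] = {}
    for se in events:
        groups.setdefault(se.group_key, []).append(se)
    for members in groups.values():
        if len(members) < 2:
            for se in members:
                se.z = 0.0
            continue
        vals = np.array([se.confidence for se in members], dtype=float)
        sd = vals.std(ddof=1)
        if sd == 0:
            for se in members:
                se.z = 0.0
            continue
        mean = vals.mean()
        for se in members:
            se.z = float((se.confidence - mean) / sd)
    return list(events)


def select_band(events: Sequence[ScoredEvent], lo: float, hi: float,
                n: int, seed: int = 0) -> list[ScoredEvent]:
    """Uniform random sample of up to ``n`` events with normalized
    confidence in the half-open band [lo, hi)."""
    if not lo < hi:
        raise ValueError("band bounds must satisfy lo < hi")
    band = [se for se in events if lo <= se.z < hi]
    if len(band) <= n:
        return list(band)
    rng = random.Random(seed)
    picked = set(rng.sample(range(len(band)), n))
    return [se for i, se in enumerate(band) if i in picked]


def select_even_distribution(events: Sequence[ScoredEvent],
                             band: tuple[float, float] = (1.5, 2.5),
                             per_group_cap: int = 2000,
                             seed: int = 0) -> list[ScoredEvent]:
    """Sample up to ``per_group_cap`` events per (type, #entity-args,
    #event-args) group within the confidence band, then add the transitive
    closure over nested event arguments regardless of band so event
    structures stay complete; closure events are flagged."""
    lo, hi = band
    by_id = {id(se.event): se for se in events}
    groups: dict[tuple, list[ScoredEvent]] = {}
    for se in events:
        if lo <= se.z < hi:
            groups.setdefault(se.group_key, []).append(se)
    rng = random.Random(seed)
    selected: list[ScoredEvent] = []
    selected_ids: set[int] = set()
    for key in sorted(groups):
        members = groups[key]
        if len(members) > per_group_cap:
            picked = set(rng.sample(range(len(members)), per_group_cap))
            members = [se for i, se in enumerate(members) if i in picked]
        for se in members:
            if id(se.event) not in selected_ids:
                selected_ids.add(id(se.event))
                selected.append(se)
    # nested closure
    queue = [se.event for se in selected]
    while queue:
        ev = queue.pop()
        for _, target in ev.event_args():
            if id(target) in selected_ids:
                continue
            selected_ids.add(id(target))
            se = by_id.get(id(target))
            if se is None:
                se = ScoredEvent(event=target, confidence=float("nan"))
            se.from_closure = True
            selected.append(se)
            queue.append(target)
    return selected
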