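"""Unmerging: pulling merged trigger nodes apart into individual events.

The trigger detector predicts at most one node per (token, type), so
overlapping events collapse into merged nodes pooling all argument edges.
An example is constructed for each argument-edge combination of each
predicted node and classified as a true event or a false event to be
removed; a final rule-based validation step deletes structurally invalid
events. Triggerless events (single edges) bypass unmerging entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

from eventex.features import (
    SparseExample,
    path_ngram_features,
    trigger_node_features,
)
from eventex.graph import ArgumentEdge, EntityNode, Event, EventGraph
from eventex.learning import NEGATIVE
from eventex.schema import TaskSchema
from eventex.standoff import Sentence

MAX_CANDIDATES_PER_NODE = 64
MAX_EDGES_PER_NODE = 10
POSITIVE_LABEL = "event"


@dataclass
class EventCandidate:
    node: EntityNode
    arguments: tuple[ArgumentEdge, ...]     # subset of outgoing core edges
    example: SparseExample | None = None
    confidence: float = 0.0                 # classifier decision score


def _counts_ok(schema: TaskSchema, event_type: str,
               role_counts: dict[str, int]) -> bool:
    roles = schema.event_types.get(event_type)
    if roles is None:
        return False
    for role, spec in roles.items():
        n = role_counts.get(role, 0)
        if n < spec.min_count:
            return False
        if spec.max_count is not None and n > spec.max_count:
            return False
    return not any(r not in roles for r in role_counts)


def enumerate_candidates(node: EntityNode, outgoing: list[ArgumentEdge],
                         schema: TaskSchema) -> list[EventCandidate]:
    """All subsets of a merged node's outgoing core edges that satisfy the
    schema's role cardinalities.

    Site edges are excluded upstream in protein-linked mode. The empty
    subset is a candidate only for zero-argument event types. The subset
    count is capped; past the cap, subsets with the highest summed edge
    confidence are kept.
    """
    if node.type not in schema.event_types:
        return []
    roles = schema.event_types[node.type]
    core = [e for e in outgoing
            if e.type in roles and not (roles[e.type].site
                                        and schema.site_mode == "protein-linked")]
    if len(core) > MAX_EDGES_PER_NODE:
        warnings.warn(f"node {node.node_id}: {len(core)} outgoing edges, "
                      f"keeping the {MAX_EDGES_PER_NODE} most confident")
        core = sorted(core, key=lambda e: (-e.confidence, e.key()))
        core = sorted(core[:MAX_EDGES_PER_NODE], key=lambda e: e.key())

    candidates: list[EventCandidate] = []
    for r in range(len(core) + 1):
        for subset in combinations(core, r):
            counts: dict[str, int] = {}
            for e in subset:
                counts[e.type] = counts.get(e.type, 0) + 1
            if not _counts_ok(schema, node.type, counts):
                continue
            if r == 0 and node.type not in schema.zero_argument_types:
                continue
            candidates.append(EventCandidate(node=node, arguments=subset))
    if len(candidates) > MAX_CANDIDATES_PER_NODE:
        warnings.warn(f"node {node.node_id}: candidate cap exceeded "
                      f"({len(candidates)}), pruning by edge confidence")
        candidates.sort(key=lambda c: (-sum(e.confidence for e in c.arguments),
                                       tuple(e.key() for e in c.arguments)))
        candidates = candidates[:MAX_CANDIDATES_PER_NODE]
    candidates.sort(key=lambda c: tuple(e.key() for e in c.arguments))
    return candidates


def candidate_features(candidate: EventCandidate, graph: EventGraph,
                       sentence: Sentence, schema: TaskSchema
                       ) -> dict[str, float]:
    f = trigger_node_features(candidate.node, schema, prefix="trig_")
    f[f"nArgs={len(candidate.arguments)}"] = 1.0
    role_counts: dict[str, int] = {}
    for e in candidate.arguments:
        role_counts[e.type] = role_counts.get(e.type, 0) + 1
        target = graph.nodes.get(e.target)
        if target is None:
            continue
        f[f"arg:{e.type}={target.type}"] = 1.0
        f.update(path_ngram_features(candidate.node, target, sentence,
                                     prefix=f"arg{e.type}_"))
    for role, n in role_counts.items():
        f[f"n{role}={n}"] = 1.0
    # edges left out of the combination also describe it
    return f


def gold_candidate_label(candidate: EventCandidate, graph: EventGraph) -> str:
    """Positive iff some gold event merged into this node has exactly the
    candidate's (role, target-node) multiset. Labels are derived on the
    merged gold graph, matching argument targets by merged node identity."""
    node_id = candidate.node.node_id
    want = sorted((e.type, e.target) for e in candidate.arguments)
    for ev in graph.events:
        if graph.event_node.get(id(ev)) != node_id:
            continue
        have = []
        ok = True
        for role, target in ev.arguments:
            if isinstance(target, Event):
                tid = graph.event_node.get(id(target))
                if tid is None:
                    ok = False
                    break
                have.append((role, tid))
            else:
                have.append((role, target.node_id))
        if ok and sorted(have) == want:
            return POSITIVE_LABEL
    return NEGATIVE


def generate_unmerge_examples(graph: EventGraph, sentence: Sentence,
                              doc_id: str, schema: TaskSchema,
                              labeled: bool = True
                              ) -> list[tuple[EventCandidate, SparseExample]]:
    out = []
    roles_by_type = schema.event_types
    for node in sorted(graph.nodes.values(), key=lambda n: n.node_id):
        if node.given or node.type not in roles_by_type:
            continue
        outgoing = graph.outgoing(node.node_id)
        for k, cand in enumerate(enumerate_candidates(node, outgoing, schema)):
            label = gold_candidate_label(cand, graph) if labeled else NEGATIVE
            ex = SparseExample(
                example_id=f"{doc_id}.s{sentence.index}.u.{node.node_id}.{k}",
                features=candidate_features(cand, graph, sentence, schema),
                label=label,
                provenance=(doc_id, sentence.index, node.node_id))
            cand.example = ex
            out.append((cand, ex))
    return out


def assemble_events(graph: EventGraph, accepted: list[EventCandidate],
                    schema: TaskSchema) -> list[Event]:
    """Build Event objects from accepted candidates plus triggerless
    relation edges.

    An argument edge targeting another trigger node expands over every
    accepted event at that node (events reference events, not nodes);
    candidates whose target node produced no event are dropped — the same
    cascade the validation step applies.
    """
    by_node: dict[str, list[EventCandidate]] = {}
    for cand in accepted:
        by_node.setdefault(cand.node.node_id, []).append(cand)

    events_at: dict[str, list[Event]] = {}
    building: set[str] = set()
    counter = [0]

    def events_for_node(node_id: str) -> list[Event]:
        if node_id in events_at:
            return events_at[node_id]
        if node_id in building:   # cyclic edge structure: break the loop
            return []
        building.add(node_id)
        result: list[Event] = []
        for cand in by_node.get(node_id, ()):
            slot_options: list[list[tuple[str, object]]] = []
            feasible = True
            for e in cand.arguments:
                target = graph.nodes.get(e.target)
                if target is None:
                    feasible = False
                    break
                if target.given or target.type not in schema.event_types:
                    slot_options.append([(e.type, target)])
                else:
                    child_events = events_for_node(e.target)
                    if not child_events:
                        feasible = False
                        break
                    slot_options.append([(e.type, c) for c in child_events])
            if not feasible:
                continue
            combos: list[list[tuple[str, object]]] = [[]]
            for options in slot_options:
                combos = [c + [o] for c in combos for o in options]
                if len(combos) > 8:   # cap nested cross-products
                    combos = combos[:8]
            for args in combos:
                counter[0] += 1
                result.append(Event(
                    event_id=f"U{counter[0]}", type=cand.node.type,
                    trigger=cand.node, arguments=args,
                    confidence=cand.confidence))
        building.discard(node_id)
        events_at[node_id] = result
        return result

    for node_id in sorted(by_node):
        events_for_node(node_id)
    out = [ev for evs in events_at.values() for ev in evs]

    # triggerless events from relation-type edges
    for e in graph.edges:
        if e.type not in schema.relation_types:
            continue
        roles = schema.relation_types[e.type]
        src = graph.nodes.get(e.source)
        dst = graph.nodes.get(e.target)
        if src is None or dst is None or len(roles) < 2:
            continue
        counter[0] += 1
        out.append(Event(event_id=f"U{counter[0]}", type=e.type, trigger=None,
                         arguments=[(roles[0].role, src), (roles[1].role, dst)],
                         confidence=e.confidence))
    return out


def validate_events(events: list[Event], schema: TaskSchema
                    ) -> tuple[list[Event], float]:
    """Remove structurally incorrect events: wrong roles or target types,
    cardinality violations, events whose nested argument event was itself
    removed (cascading to a fixed point), and duplicates. Returns the kept
    events and the fraction removed."""
    total = len(events)
    kept = {id(ev): ev for ev in events}

    def structurally_valid(ev: Event) -> bool:
        if ev.trigger is None:
            roles = schema.relation_types.get(ev.type)
            if roles is None:
                return False
            if len(ev.arguments) != len(roles):
                return False
            for (role, target), spec in zip(ev.arguments, roles):
                if role != spec.role or isinstance(target, Event):
                    return False
                if not schema.role_accepts(spec, target.type):
                    return False
            return True
        roles = schema.event_types.get(ev.type)
        if roles is None:
            return False
        counts: dict[str, int] = {}
        for role, target in ev.arguments:
            spec = roles.get(role)
            if spec is None:
                return False
            ttype = target.type if isinstance(target, Event) else target.type
            if not schema.role_accepts(spec, ttype):
                return False
            counts[role] = counts.get(role, 0) + 1
        for role, spec in roles.items():
            n = counts.get(role, 0)
            if n < spec.min_count:
                return False
            if spec.max_count is not None and n > spec.max_count:
                return False
        if not ev.arguments and ev.type not in schema.zero_argument_types:
            return False
        return True

    changed = True
    while changed:
        changed = False
        for key in list(kept):
            ev = kept[key]
            if not structurally_valid(ev):
                del kept[key]
                changed = True
                continue
            for _, target in ev.arguments:
                if isinstance(target, Event) and id(target) not in kept:
                    del kept[key]
                    changed = True
                    break

    # deduplicate by full recursive signature
    seen = set()
    result = []
    for ev in events:
        if id(ev) not in kept:
            continue
        sig = ev.signature()
        if sig in seen:
            continue
        seen.add(sig)
        result.append(ev)
    removed_fraction = (total - len(result)) / total if total else 0.0
    return result, removed_fraction
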