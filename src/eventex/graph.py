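"""Event-graph data model.

Annotations become per-sentence graphs: trigger and protein/gene entities
are nodes, event arguments are typed directed edges, and an event is a
trigger node with its outgoing role edges (triggerless relations are a
single edge). Sentences are processed in isolation, so events whose
arguments cross a sentence boundary are excluded and counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from eventex.schema import TaskSchema
from eventex.standoff import Document, Sentence, StandoffLine


@dataclass
class EntityNode:
    node_id: str
    type: str
    head_token: int
    char_spans: list[tuple[int, int]]
    given: bool
    text: str = ""
    sentence_index: int = -1
    confidence: float = 0.0

    def span_key(self):
        return (self.type, tuple(self.char_spans))


@dataclass
class ArgumentEdge:
    source: str            # node_id
    target: str            # node_id
    type: str              # role label or relation type
    directed: bool = True
    confidence: float = 0.0

    def key(self):
        if self.directed:
            return (self.source, self.target, self.type)
        a, b = sorted((self.source, self.target))
        return (a, b, self.type)


@dataclass
class Event:
    event_id: str
    type: str
    trigger: Optional[EntityNode]                   # None for triggerless
    arguments: list[tuple[str, object]]             # (role, EntityNode | Event)
    negation: bool = False
    speculation: bool = False
    confidence: float = 0.0

    def entity_args(self):
        return [(r, t) for r, t in self.arguments if isinstance(t, EntityNode)]

    def event_args(self):
        return [(r, t) for r, t in self.arguments if isinstance(t, Event)]

    def signature(self):
        args = tuple(sorted(
            (r, t.signature() if isinstance(t, Event) else t.span_key())
            for r, t in self.arguments
        ))
        trig = self.trigger.span_key() if self.trigger is not None else None
        return (self.type, trig, args, self.negation, self.speculation)


@dataclass
class EventGraph:
    sentence_index: int
    nodes: dict[str, EntityNode] = field(default_factory=dict)
    edges: list[ArgumentEdge] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    # merged graphs: map id(event) -> merged node_id housing it
    event_node: dict[int, str] = field(default_factory=dict)

    def add_node(self, node: EntityNode) -> EntityNode:
        self.nodes[node.node_id] = node
        return node

    def outgoing(self, node_id: str) -> list[ArgumentEdge]:
        return [e for e in self.edges if e.source == node_id]


@dataclass
class BuildStats:
    intersentence_events: int = 0
    dropped_sites: int = 0


ROLE_SUFFIX = re.compile(r"^(.*?)(\d+)$")


def base_role(role: str) -> tuple[str, int]:
    """Strip the numbering convention (Theme2 -> (Theme, 2))."""
    m = ROLE_SUFFIX.match(role)
    if m and m.group(1):
        return m.group(1), int(m.group(2))
    return role, 1


def select_head_token(char_span: tuple[int, int], sentence: Sentence) -> int:
    """Head token of a span: the in-span token not governed by another
    in-span token (root of the covered parse subtree); ties and
    parse-disconnected spans resolve to the rightmost candidate."""
    s, e = char_span
    in_span = [t for t in sentence.tokens
               if t.char_start < e and t.char_end > s]
    if not in_span:
        # span/token misalignment beyond the punctuation-splitting case:
        # fall back to the nearest token by midpoint distance
        if not sentence.tokens:
            return -1
        mid = (s + e) / 2
        return min(sentence.tokens,
                   key=lambda t: (abs((t.char_start + t.char_end) / 2 - mid),
                                  t.index)).index
    if len(in_span) == 1:
        return in_span[0].index
    indices = {t.index for t in in_span}
    roots = [t.index for t in in_span
             if not any(d.dependent == t.index and d.governor in indices
                        for d in sentence.dependencies)]
    if not roots:
        roots = [t.index for t in in_span]
    return max(roots)


def _event_sentence(ev: Event) -> set[int]:
    out = set()
    if ev.trigger is not None:
        out.add(ev.trigger.sentence_index)
    for _, target in ev.arguments:
        if isinstance(target, Event):
            out |= _event_sentence(target)
        else:
            out.add(target.sentence_index)
    return out


def build_graph(doc: Document, schema: TaskSchema,
                drop_intersentence: bool = True
                ) -> tuple[list[EventGraph], BuildStats]:
    """Convert a document's standoff annotation into per-sentence graphs.

    With ``drop_intersentence=False`` events crossing sentence boundaries
    are kept (attached to the trigger's sentence) instead of excluded —
    used when collecting the full annotated gold set for evaluation."""
    stats = BuildStats()
    graphs = [EventGraph(sentence_index=s.index) for s in doc.sentences]

    nodes: dict[str, EntityNode] = {}
    for ann in doc.annotations:
        if ann.kind != "entity":
            continue
        sent = doc.sentence_at(ann.spans[0][0])
        if sent is None:
            continue
        head = select_head_token(ann.spans[0], sent)
        node = EntityNode(node_id=ann.line_id, type=ann.type, head_token=head,
                          char_spans=list(ann.spans), given=(ann.source == "a1"),
                          text=ann.text, sentence_index=sent.index)
        nodes[ann.line_id] = node
        graphs[sent.index].add_node(node)

    # events: two passes so forward references between E lines resolve
    event_anns = {a.line_id: a for a in doc.annotations if a.kind == "event"}
    relation_anns = {a.line_id: a for a in doc.annotations if a.kind == "relation"}
    events: dict[str, Event] = {}

    def build_event(eid: str, stack: tuple = ()) -> Optional[Event]:
        if eid in events:
            return events[eid]
        if eid in stack:
            return None  # cyclic reference: malformed, drop
        ann = event_anns.get(eid) or relation_anns.get(eid)
        if ann is None:
            return None
        trigger = nodes.get(ann.trigger) if ann.trigger else None
        args: list[tuple[str, object]] = []
        for role, target_id in ann.args:
            role_name, _ = base_role(role)
            if target_id in nodes:
                args.append((role_name, nodes[target_id]))
            else:
                child = build_event(target_id, stack + (eid,))
                if child is None:
                    return None
                args.append((role_name, child))
        ev = Event(event_id=eid, type=ann.type, trigger=trigger, arguments=args)
        events[eid] = ev
        return ev

    for eid in list(event_anns) + list(relation_anns):
        build_event(eid)

    # modality
    for ann in doc.annotations:
        if ann.kind == "modifier" and ann.args:
            target = events.get(ann.args[0][1])
            if target is not None:
                if ann.type == "Negation":
                    target.negation = True
                elif ann.type == "Speculation":
                    target.speculation = True

    # sentence isolation: drop events spanning several sentences (cascades
    # through nesting because _event_sentence is recursive)
    kept: dict[str, Event] = {}
    for eid, ev in events.items():
        sents = _event_sentence(ev)
        if len(sents) == 1 or not drop_intersentence:
            kept[eid] = ev
            if len(sents) > 1:
                stats.intersentence_events += 1
        else:
            stats.intersentence_events += 1
    # drop events whose nested argument was itself dropped
    changed = True
    while changed:
        changed = False
        for eid in list(kept):
            ev = kept[eid]
            for _, target in ev.arguments:
                if isinstance(target, Event) and target.event_id not in kept:
                    del kept[eid]
                    changed = True
                    break

    for ev in kept.values():
        if ev.trigger is not None and ev.trigger.sentence_index >= 0:
            sent_index = ev.trigger.sentence_index
        else:
            sent_index = min(s for s in _event_sentence(ev) if s >= 0)
        graph = graphs[sent_index]
        graph.events.append(ev)
        _add_event_edges(graph, ev, schema)

    for g in graphs:
        g.events.sort(key=lambda e: e.event_id)
        seen = set()
        uniq = []
        for e in g.edges:
            if e.key() not in seen:
                seen.add(e.key())
                uniq.append(e)
        g.edges = uniq
    return graphs, stats


def _core_target_for_site(ev: Event, role: str, position: int) -> Optional[EntityNode]:
    """Pair a site-style argument with its core argument's protein target.

    Pairing follows the numbering convention (Site2 with Theme2); when an
    event has a single core argument the pairing is unambiguous."""
    cores = [(r, t) for r, t in ev.arguments if isinstance(t, EntityNode)]
    cores = [(r, t) for r, t in cores if r in ("Theme", "Cause", "Participant")]
    if not cores:
        return None
    if position < len(cores):
        return cores[position][1]
    return cores[0][1]


def _add_event_edges(graph: EventGraph, ev: Event, schema: TaskSchema) -> None:
    if ev.trigger is None:
        if len(ev.arguments) >= 2:
            src = ev.arguments[0][1]
            dst = ev.arguments[1][1]
            if isinstance(src, EntityNode) and isinstance(dst, EntityNode):
                directed = ev.type not in schema.undirected_relation_types
                graph.edges.append(ArgumentEdge(src.node_id, dst.node_id,
                                                ev.type, directed=directed))
        return
    roles = schema.event_types.get(ev.type, {})
    site_positions: dict[str, int] = {}
    for role, target in ev.arguments:
        spec = roles.get(role)
        is_site = spec.site if spec is not None else False
        if isinstance(target, Event):
            dst = target.trigger
            if dst is None:
                continue
            graph.edges.append(ArgumentEdge(ev.trigger.node_id, dst.node_id, role))
        elif is_site and schema.site_mode == "protein-linked":
            pos = site_positions.get(role, 0)
            site_positions[role] = pos + 1
            core = _core_target_for_site(ev, role, pos)
            if core is None:
                continue
            graph.edges.append(ArgumentEdge(core.node_id, target.node_id, role))
        else:
            graph.edges.append(ArgumentEdge(ev.trigger.node_id, target.node_id, role))


def resolve_equivalences(graphs: list[EventGraph],
                         equiv_sets: Iterable[list[str]],
                         schema: TaskSchema | None = None) -> list[EventGraph]:
    """Duplicate events across equivalent entity mentions.

    Every event referencing a member of an equivalence set is duplicated for
    each substitution of equivalent members, recursively when a duplicated
    event is nested in another event; the result is deduplicated.
    """
    classes: dict[str, list[str]] = {}
    for members in equiv_sets:
        for m in members:
            classes[m] = list(members)

    for graph in graphs:
        def options(node: EntityNode) -> list[EntityNode]:
            ids = classes.get(node.node_id)
            if not ids:
                return [node]
            opts = [graph.nodes[i] for i in ids if i in graph.nodes]
            return opts or [node]

        memo: dict[int, list[Event]] = {}

        def variants(ev: Event) -> list[Event]:
            if id(ev) in memo:
                return memo[id(ev)]
            slot_options: list[list[tuple[str, object]]] = []
            for role, target in ev.arguments:
                if isinstance(target, Event):
                    slot_options.append([(role, v) for v in variants(target)])
                else:
                    slot_options.append([(role, n) for n in options(target)])
            results: list[Event] = []
            def expand(i: int, acc: list):
                if i == len(slot_options):
                    results.append(Event(
                        event_id=ev.event_id, type=ev.type, trigger=ev.trigger,
                        arguments=list(acc), negation=ev.negation,
                        speculation=ev.speculation, confidence=ev.confidence))
                    return
                for choice in slot_options[i]:
                    acc.append(choice)
                    expand(i + 1, acc)
                    acc.pop()
            expand(0, [])
            memo[id(ev)] = results
            return results

        out: list[Event] = []
        seen = set()
        counter = 0
        for ev in graph.events:
            for v in variants(ev):
                sig = v.signature()
                if sig not in seen:
                    seen.add(sig)
                    if v is not ev:
                        counter += 1
                        v.event_id = f"{ev.event_id}.eq{counter}"
                    out.append(v)
        graph.events = out
        # refresh edges from the expanded event set
        graph.edges = []
        if schema is not None:
            for ev in graph.events:
                _add_event_edges(graph, ev, schema)
            seen_keys = set()
            uniq = []
            for e in graph.edges:
                if e.key() not in seen_keys:
                    seen_keys.add(e.key())
                    uniq.append(e)
            graph.edges = uniq
        else:
            schema_less_edges(graph)
    return graphs


def schema_less_edges(graph: EventGraph) -> None:
    """Rebuild plain argument edges (no site remapping) from graph.events."""
    seen = set()
    for ev in graph.events:
        if ev.trigger is None:
            if len(ev.arguments) >= 2 and all(
                    isinstance(t, EntityNode) for _, t in ev.arguments[:2]):
                e = ArgumentEdge(ev.arguments[0][1].node_id,
                                 ev.arguments[1][1].node_id, ev.type)
                if e.key() not in seen:
                    seen.add(e.key())
                    graph.edges.append(e)
            continue
        for role, target in ev.arguments:
            dst = target.trigger if isinstance(target, Event) else target
            if dst is None:
                continue
            e = ArgumentEdge(ev.trigger.node_id, dst.node_id, role)
            if e.key() not in seen:
                seen.add(e.key())
                graph.edges.append(e)


def to_merged_graph(graphs: list[EventGraph], schema: TaskSchema) -> list[EventGraph]:
    """Collapse overlapping events into merged trigger nodes.

    At most one trigger node per (head token, type) remains per sentence;
    the outgoing argument edges of the merged events are pooled and
    deduplicated. Mirrors the capacity of the trigger detector, which
    predicts a maximum of one trigger node per type for each token.
    """
    merged_graphs = []
    for graph in graphs:
        mg = EventGraph(sentence_index=graph.sentence_index)
        for node in graph.nodes.values():
            if node.given:
                mg.add_node(node)
        merged_key_to_node: dict[tuple[int, str], EntityNode] = {}

        def merged_node_for(node: EntityNode) -> EntityNode:
            if node.given:
                return node
            key = (node.head_token, node.type)
            if key not in merged_key_to_node:
                m = EntityNode(node_id=f"M{len(merged_key_to_node) + 1}."
                                       f"{graph.sentence_index}",
                               type=node.type, head_token=node.head_token,
                               char_spans=list(node.char_spans), given=False,
                               text=node.text,
                               sentence_index=node.sentence_index)
                merged_key_to_node[key] = m
                mg.add_node(m)
            return merged_key_to_node[key]

        # make merged nodes for every non-given node (triggers and
        # predicted entities), preserving type distinctions on one token
        for node in graph.nodes.values():
            if not node.given:
                merged_node_for(node)

        seen = set()
        for ev in graph.events:
            if ev.trigger is None:
                mg.events.append(ev)
                continue
            src = merged_node_for(ev.trigger)
            mg.event_node[id(ev)] = src.node_id
            mg.events.append(ev)
        # pool edges, remapping endpoints to merged nodes
        for e in graph.edges:
            src = graph.nodes.get(e.source)
            dst = graph.nodes.get(e.target)
            if src is None or dst is None:
                continue
            me = ArgumentEdge(merged_node_for(src).node_id,
                              merged_node_for(dst).node_id,
                              e.type, directed=e.directed)
            if me.key() not in seen:
                seen.add(me.key())
                mg.edges.append(me)
        merged_graphs.append(mg)
    return merged_graphs


def pair_sites_on_output(events: list[Event], site_edges: list[ArgumentEdge],
                         graph: EventGraph, schema: TaskSchema
                         ) -> tuple[list[Event], int]:
    """Attach site arguments to output events.

    In protein-linked mode each site edge (protein -> site entity, typed by
    the site role) is attached as a site argument of every event whose core
    argument targets that protein at the same sentence graph; a site edge
    with no matching core argument is dropped and counted. In trigger-linked
    mode sites are already ordinary event arguments and pass through.
    """
    if schema.site_mode != "protein-linked":
        return events, 0
    dropped = 0
    for edge in site_edges:
        protein = graph.nodes.get(edge.source)
        site = graph.nodes.get(edge.target)
        if protein is None or site is None:
            dropped += 1
            continue
        matched = False
        for ev in events:
            if ev.trigger is None:
                continue
            roles = schema.event_types.get(ev.type, {})
            spec = roles.get(edge.type)
            if spec is None or not spec.site:
                continue
            for _, target in ev.entity_args():
                if target is protein:
                    ev.arguments.append((edge.type, site))
                    matched = True
                    break
        if not matched:
            dropped += 1
    return events, dropped
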