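"""Event-graph construction, head selection, equivalence resolution and
merged-graph pooling."""

import itertools
import random

import pytest

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
from tests.conftest import make_entity, make_event, make_sentence
from tests.test_standoff import write_doc


class TestBuildGraph:
    def test_regulation_over_phosphorylation(self, tmp_path, ge_schema):
        # "Stat3 phosphorylation is regulated by Vav"
        doc = write_doc(
            tmp_path, "Stat3 phosphorylation is regulated by Vav\n",
            a1="T1\tProtein 0 5\tStat3\nT2\tProtein 38 41\tVav\n",
            a2="T3\tPhosphorylation 6 21\tphosphorylation\n"
               "T4\tRegulation 25 34\tregulated\n"
               "E1\tPhosphorylation:T3 Theme:T1\n"
               "E2\tRegulation:T4 Theme:E1 Cause:T2\n")
        graphs, stats = build_graph(doc, ge_schema)
        (g,) = graphs
        by_type = {}
        for e in g.edges:
            by_type.setdefault(e.type, []).append((e.source, e.target))
        assert ("T4", "T3") in by_type["Theme"]
        assert ("T4", "T2") in by_type["Cause"]
        assert ("T3", "T1") in by_type["Theme"]
        assert stats.intersentence_events == 0

    def test_relation_is_single_edge_without_trigger(self, tmp_path,
                                                     ren_schema):
        doc = write_doc(tmp_path, "yabA renamed to orf12\n",
                        a1="T1\tGene 0 4\tyabA\nT2\tGene 16 21\torf12\n",
                        a2="R1\tRenaming Former:T1 New:T2\n")
        graphs, _ = build_graph(doc, ren_schema)
        (g,) = graphs
        assert len(g.edges) == 1
        assert g.edges[0].type == "Renaming"
        assert g.events[0].trigger is None

    def test_intersentence_event_excluded_and_counted(self, tmp_path,
                                                      ge_schema):
        doc = write_doc(
            tmp_path, "ABC1 regulates this\nDEF2 is expressed\n",
            a1="T1\tProtein 0 4\tABC1\nT2\tProtein 20 24\tDEF2\n",
            a2="T3\tRegulation 5 14\tregulates\n"
               "T4\tGene_expression 28 37\texpressed\n"
               "E1\tGene_expression:T4 Theme:T2\n"
               "E2\tRegulation:T3 Theme:E1 Cause:T1\n")
        graphs, stats = build_graph(doc, ge_schema)
        assert stats.intersentence_events == 1
        all_events = [ev for g in graphs for ev in g.events]
        assert {ev.type for ev in all_events} == {"Gene_expression"}
        # every kept event's nodes share one sentence
        for g in graphs:
            for ev in g.events:
                sents = {ev.trigger.sentence_index} | {
                    t.sentence_index for _, t in ev.entity_args()}
                assert sents == {g.sentence_index}


class TestSelectHeadToken:
    def test_single_token_span(self):
        sent = make_sentence("Vav binds Stat3", deps=[(1, 0, "nsubj"),
                                                      (1, 2, "dobj")])
        tok = sent.tokens[0]
        assert select_head_token((tok.char_start, tok.char_end), sent) == 0

    def test_subtree_root_of_multiword_span(self):
        sent = make_sentence("tumor necrosis factor binds",
                             deps=[(2, 0, "nn"), (2, 1, "nn"),
                                   (3, 2, "nsubj")])
        span = (sent.tokens[0].char_start, sent.tokens[2].char_end)
        assert select_head_token(span, sent) == 2

    def test_disconnected_span_falls_back_to_rightmost(self):
        sent = make_sentence("alpha beta gamma", deps=[])
        span = (sent.tokens[0].char_start, sent.tokens[1].char_end)
        assert select_head_token(span, sent) == 1


def brute_force_resolution(events, classes):
    """Independent oracle: enumerate every assignment of equivalence-class
    members to the entity slots of each event tree, construct the
    substituted events, and deduplicate."""

    def slots(ev, path=()):
        found = []
        for i, (role, target) in enumerate(ev.arguments):
            if isinstance(target, Event):
                found.extend(slots(target, path + (i,)))
            else:
                found.append((path + (i,), target))
        return found

    def substitute(ev, assignment, path=()):
        new_args = []
        for i, (role, target) in enumerate(ev.arguments):
            if isinstance(target, Event):
                new_args.append((role, substitute(target, assignment,
                                                  path + (i,))))
            else:
                new_args.append((role, assignment[path + (i,)]))
        return Event(event_id=ev.event_id, type=ev.type, trigger=ev.trigger,
                     arguments=new_args, negation=ev.negation,
                     speculation=ev.speculation)

    out = {}
    for ev in events:
        sl = slots(ev)
        option_lists = []
        for path, node in sl:
            opts = classes.get(node.node_id, [node])
            option_lists.append([(path, o) for o in opts])
        for combo in itertools.product(*option_lists):
            new = substitute(ev, dict(combo))
            out[new.signature()] = new
    return sorted(out)


def random_graph_with_equivs(rng, schema):
    """A random one-sentence graph: entities, up to 3-member equiv sets,
    simple events and nested events up to 3 levels."""
    sent = make_sentence(" ".join(f"w{i}" for i in range(12)))
    g = EventGraph(sentence_index=0)
    n_ent = rng.randint(1, 4)
    entities = []
    for i in range(n_ent):
        node = make_entity(f"T{i + 1}", "Protein", sent, i)
        g.add_node(node)
        entities.append(node)
    equiv_sets = []
    pool = list(entities)
    while len(pool) >= 2 and rng.random() < 0.6:
        k = rng.randint(2, min(3, len(pool)))
        members = rng.sample(pool, k)
        for m in members:
            pool.remove(m)
        equiv_sets.append([m.node_id for m in members])
    events = []
    n_simple = rng.randint(1, 3)
    for k in range(n_simple):
        trig = make_entity(f"TT{k + 1}", "Gene_expression", sent,
                           rng.randrange(len(sent.tokens)), given=False)
        g.add_node(trig)
        ev = make_event(f"E{k + 1}", "Gene_expression", trig,
                        ("Theme", rng.choice(entities)))
        events.append(ev)
    # up to two nesting levels on top
    for lvl in range(rng.randint(0, 2)):
        if not events:
            break
        trig = make_entity(f"TR{lvl}", "Regulation", sent,
                           rng.randrange(len(sent.tokens)), given=False)
        g.add_node(trig)
        args = [("Theme", rng.choice(events))]
        if entities and rng.random() < 0.7:
            args.append(("Cause", rng.choice(entities)))
        events.append(make_event(f"ER{lvl}", "Regulation", trig, *args))
    g.events = events
    return g, equiv_sets


class TestResolveEquivalences:
    def test_simple_duplication(self, ge_schema):
        sent = make_sentence("caspase8 casp8 is ubiquitinated")
        g = EventGraph(sentence_index=0)
        c8 = make_entity("T1", "Protein", sent, 0)
        c8b = make_entity("T2", "Protein", sent, 1)
        trig = make_entity("T3", "Protein_catabolism", sent, 3, given=False)
        for n in (c8, c8b, trig):
            g.add_node(n)
        g.events = [make_event("E1", "Protein_catabolism", trig,
                               ("Theme", c8))]
        resolve_equivalences([g], [["T1", "T2"]], ge_schema)
        assert len(g.events) == 2
        themes = {ev.arguments[0][1].node_id for ev in g.events}
        assert themes == {"T1", "T2"}

    def test_recursive_duplication_through_nesting(self, ge_schema):
        sent = make_sentence("caspase8 casp8 x regulated ubiquitinated")
        g = EventGraph(sentence_index=0)
        c8 = make_entity("T1", "Protein", sent, 0)
        c8b = make_entity("T2", "Protein", sent, 1)
        ub = make_entity("T3", "Protein_catabolism", sent, 4, given=False)
        rg = make_entity("T4", "Regulation", sent, 3, given=False)
        for n in (c8, c8b, ub, rg):
            g.add_node(n)
        inner = make_event("E1", "Protein_catabolism", ub, ("Theme", c8))
        outer = make_event("E2", "Regulation", rg, ("Theme", inner))
        g.events = [inner, outer]
        resolve_equivalences([g], [["T1", "T2"]], ge_schema)
        assert sum(1 for ev in g.events if ev.type == "Regulation") == 2

    def test_no_equiv_sets_is_identity(self, ge_schema):
        sent = make_sentence("A B expressed")
        g = EventGraph(sentence_index=0)
        a = make_entity("T1", "Protein", sent, 0)
        trig = make_entity("T2", "Gene_expression", sent, 2, given=False)
        g.add_node(a)
        g.add_node(trig)
        g.events = [make_event("E1", "Gene_expression", trig, ("Theme", a))]
        before = sorted(ev.signature() for ev in g.events)
        resolve_equivalences([g], [], ge_schema)
        assert sorted(ev.signature() for ev in g.events) == before

    def test_matches_brute_force_oracle_on_random_graphs(self, ge_schema):
        rng = random.Random(17)
        for _ in range(500):
            g, equiv_sets = random_graph_with_equivs(rng, ge_schema)
            classes = {}
            for members in equiv_sets:
                for m in members:
                    classes[m] = [g.nodes[x] for x in members]
            expected = brute_force_resolution(g.events, classes)
            resolve_equivalences([g], equiv_sets, ge_schema)
            got = sorted(ev.signature() for ev in g.events)
            assert got == expected


class TestMergedGraph:
    def test_two_bindings_same_trigger_pool_edges(self, ge_schema):
        sent = make_sentence("P1 binds P2 and P3",
                             deps=[(1, 0, "nsubj"), (1, 2, "dobj"),
                                   (1, 4, "dobj")])
        g = EventGraph(sentence_index=0)
        p1 = make_entity("T1", "Protein", sent, 0)
        p2 = make_entity("T2", "Protein", sent, 2)
        p3 = make_entity("T3", "Protein", sent, 4)
        b1 = make_entity("T4", "Binding", sent, 1, given=False)
        b2 = make_entity("T5", "Binding", sent, 1, given=False)
        for n in (p1, p2, p3, b1, b2):
            g.add_node(n)
        g.events = [make_event("E1", "Binding", b1, ("Theme", p2)),
                    make_event("E2", "Binding", b2, ("Theme", p3))]
        from eventex.graph import schema_less_edges
        schema_less_edges(g)
        (mg,) = to_merged_graph([g], ge_schema)
        merged_triggers = [n for n in mg.nodes.values() if not n.given]
        assert len(merged_triggers) == 1
        edges = {(e.type, mg.nodes[e.target].node_id) for e in mg.edges}
        assert edges == {("Theme", "T2"), ("Theme", "T3")}

    def test_different_types_on_one_token_stay_separate(self, ge_schema):
        sent = make_sentence("P1 induces P2",
                             deps=[(1, 0, "nsubj"), (1, 2, "dobj")])
        g = EventGraph(sentence_index=0)
        p1 = make_entity("T1", "Protein", sent, 0)
        p2 = make_entity("T2", "Protein", sent, 2)
        ge = make_entity("T3", "Gene_expression", sent, 1, given=False)
        pr = make_entity("T4", "Positive_regulation", sent, 1, given=False)
        for n in (p1, p2, ge, pr):
            g.add_node(n)
        inner = make_event("E1", "Gene_expression", ge, ("Theme", p2))
        outer = make_event("E2", "Positive_regulation", pr,
                           ("Theme", inner), ("Cause", p1))
        g.events = [inner, outer]
        from eventex.graph import schema_less_edges
        schema_less_edges(g)
        (mg,) = to_merged_graph([g], ge_schema)
        assert len([n for n in mg.nodes.values() if not n.given]) == 2

    def test_no_argument_edge_lost_in_pooling(self, ge_schema, rng):
        # pooled merged edges equal the union of per-event argument edges
        sent = make_sentence(" ".join(f"w{i}" for i in range(8)))
        g = EventGraph(sentence_index=0)
        prots = [make_entity(f"T{i}", "Protein", sent, i) for i in range(4)]
        for p in prots:
            g.add_node(p)
        trig = make_entity("T9", "Binding", sent, 5, given=False)
        g.add_node(trig)
        g.events = [
            make_event(f"E{i}", "Binding", trig,
                       *[("Theme", p) for p in rng.sample(prots,
                                                          rng.randint(1, 3))])
            for i in range(3)
        ]
        from eventex.graph import schema_less_edges
        schema_less_edges(g)
        want = {("Theme", t.node_id)
                for ev in g.events for _, t in ev.entity_args()
                for t in [t]}
        (mg,) = to_merged_graph([g], ge_schema)
        got = {(e.type, mg.nodes[e.target].node_id) for e in mg.edges}
        assert got == want


class TestSitePairing:
    def _setup(self):
        sent = make_sentence("P1 phosphorylated at Ser15",
                             deps=[(1, 0, "nsubjpass"), (1, 3, "prep_at")])
        g = EventGraph(sentence_index=0)
        p1 = make_entity("T1", "Protein", sent, 0)
        site = make_entity("T2", "Entity", sent, 3, given=False)
        trig = make_entity("T3", "Phosphorylation", sent, 1, given=False)
        for n in (p1, site, trig):
            g.add_node(n)
        return sent, g, p1, site, trig

    def test_site_attached_to_matching_event(self, ge_schema):
        sent, g, p1, site, trig = self._setup()
        ev = make_event("E1", "Phosphorylation", trig, ("Theme", p1))
        site_edges = [ArgumentEdge("T1", "T2", "Site")]
        events, dropped = pair_sites_on_output([ev], site_edges, g, ge_schema)
        assert dropped == 0
        assert ("Site", site) in events[0].arguments

    def test_ambiguous_site_attached_to_all_candidates(self, ge_schema):
        sent, g, p1, site, trig = self._setup()
        trig2 = make_entity("T4", "Phosphorylation", sent, 1, given=False)
        g.add_node(trig2)
        ev1 = make_event("E1", "Phosphorylation", trig, ("Theme", p1))
        ev2 = make_event("E2", "Phosphorylation", trig2, ("Theme", p1))
        events, dropped = pair_sites_on_output(
            [ev1, ev2], [ArgumentEdge("T1", "T2", "Site")], g, ge_schema)
        assert all(("Site", site) in ev.arguments for ev in events)

    def test_unmatched_site_dropped_and_counted(self, ge_schema):
        sent, g, p1, site, trig = self._setup()
        other = make_entity("T5", "Protein", sent, 2)
        g.add_node(other)
        ev = make_event("E1", "Phosphorylation", trig, ("Theme", p1))
        events, dropped = pair_sites_on_output(
            [ev], [ArgumentEdge("T5", "T2", "Site")], g, ge_schema)
        assert dropped == 1
        assert ("Site", site) not in events[0].arguments

    def test_no_site_edges_leaves_events_unchanged(self, ge_schema):
        sent, g, p1, site, trig = self._setup()
        ev = make_event("E1", "Phosphorylation", trig, ("Theme", p1))
        events, dropped = pair_sites_on_output([ev], [], g, ge_schema)
        assert events[0].arguments == [("Theme", p1)]
        assert dropped == 0
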