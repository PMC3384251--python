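"""Detection-stage example generation, merged-class handling, and the
EPI reverse-type and bacterium span-extension rule systems."""

import pytest

from eventex.graph import EventGraph
from eventex.learning import NEGATIVE
from eventex.stages import (
    EPI_REVERSE_TYPES,
    bb_extend_span,
    epi_reverse_rule,
    generate_edge_examples,
    generate_modality_examples,
    generate_trigger_examples,
    merge_class_label,
    split_class_label,
    split_merged_predictions,
)
from tests.conftest import make_entity, make_event, make_sentence


class TestMergedClassLabels:
    @pytest.mark.parametrize("components", [
        ["Phosphorylation"],
        ["Phosphorylation", "Regulation"],
        ["A", "C", "B"],
    ])
    def test_split_recovers_components(self, components):
        label = merge_class_label(components)
        assert split_class_label(label) == sorted(set(components))

    def test_empty_components_render_negative(self):
        assert merge_class_label([]) == NEGATIVE
        assert split_class_label(NEGATIVE) == []


class TestTriggerExamples:
    def _sentence_graph(self, ge_schema):
        sent = make_sentence("ABC1 induces DEF2 .",
                             deps=[(1, 0, "nsubj"), (1, 2, "dobj"),
                                   (1, 3, "punct")],
                             pos=["NNP", "VBZ", "NNP", "."])
        g = EventGraph(sentence_index=0)
        p1 = make_entity("T1", "Protein", sent, 0)
        p2 = make_entity("T2", "Protein", sent, 2)
        ge = make_entity("T3", "Gene_expression", sent, 1, given=False)
        pr = make_entity("T4", "Positive_regulation", sent, 1, given=False)
        for n in (p1, p2, ge, pr):
            g.add_node(n)
        return sent, g, [p1, p2]

    def test_merged_label_for_overlapping_triggers(self, ge_schema):
        sent, g, given = self._sentence_graph(ge_schema)
        examples = generate_trigger_examples(sent, "d", g, given)
        by_token = {e.provenance[2]: e for e in examples}
        assert by_token[1].label == "Gene_expression---Positive_regulation"

    def test_tokens_inside_given_entities_excluded(self, ge_schema):
        sent, g, given = self._sentence_graph(ge_schema)
        examples = generate_trigger_examples(sent, "d", g, given)
        tokens = {e.provenance[2] for e in examples}
        assert 0 not in tokens and 2 not in tokens

    def test_all_negative_without_gold(self, ge_schema):
        sent, g, given = self._sentence_graph(ge_schema)
        examples = generate_trigger_examples(sent, "d", None, given)
        assert all(e.label == NEGATIVE for e in examples)

    def test_features_identical_with_and_without_gold(self, ge_schema):
        sent, g, given = self._sentence_graph(ge_schema)
        with_gold = generate_trigger_examples(sent, "d", g, given)
        without = generate_trigger_examples(sent, "d", None, given)
        assert [e.features for e in with_gold] == \
            [e.features for e in without]


class TestSplitMergedPredictions:
    def test_merged_prediction_yields_two_nodes(self):
        sent = make_sentence("X induces Y")
        nodes = split_merged_predictions(
            [(sent, 1, "Gene_expression---Positive_regulation", 0.7)])
        assert [(n.type, n.head_token) for n in nodes] == \
            [("Gene_expression", 1), ("Positive_regulation", 1)]

    def test_simple_prediction_single_node(self):
        sent = make_sentence("X binds Y")
        nodes = split_merged_predictions([(sent, 1, "Binding", 0.3)])
        assert len(nodes) == 1

    def test_negative_prediction_no_nodes(self):
        sent = make_sentence("X binds Y")
        assert split_merged_predictions([(sent, 1, NEGATIVE, 0.0)]) == []


class TestEdgeExamples:
    def test_trigger_to_protein_pair_is_candidate(self, ge_schema):
        sent = make_sentence("ABC1 is phosphorylated",
                             deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass")])
        g = EventGraph(sentence_index=0)
        p = make_entity("T1", "Protein", sent, 0)
        t = make_entity("T2", "Phosphorylation", sent, 2, given=False)
        g.add_node(p)
        g.add_node(t)
        examples = generate_edge_examples(g, sent, "d", ge_schema)
        pairs = {(e.provenance[2], e.provenance[3]) for e in examples}
        assert ("T2", "T1") in pairs

    def test_protein_protein_pair_filtered_out(self, ge_schema):
        sent = make_sentence("ABC1 binds DEF2")
        g = EventGraph(sentence_index=0)
        g.add_node(make_entity("T1", "Protein", sent, 0))
        g.add_node(make_entity("T2", "Protein", sent, 2))
        assert generate_edge_examples(g, sent, "d", ge_schema) == []

    def test_merged_edge_label_components_sorted(self, ge_schema):
        from eventex.graph import ArgumentEdge
        sent = make_sentence("X regulates Y",
                             deps=[(1, 0, "nsubj"), (1, 2, "dobj")])
        g = EventGraph(sentence_index=0)
        p = make_entity("T1", "Protein", sent, 2)
        t = make_entity("T2", "Regulation", sent, 1, given=False)
        g.add_node(p)
        g.add_node(t)
        g.edges = [ArgumentEdge("T2", "T1", "Theme"),
                   ArgumentEdge("T2", "T1", "Cause")]
        examples = generate_edge_examples(g, sent, "d", ge_schema)
        labels = {e.label for e in examples}
        assert "Cause---Theme" in labels

    def test_undirected_task_generates_one_example_per_pair(self, ren_schema):
        sent = make_sentence("yabA renamed orf12",
                             deps=[(1, 0, "nsubj"), (1, 2, "dobj")])
        g = EventGraph(sentence_index=0)
        g.add_node(make_entity("T1", "Gene", sent, 0))
        g.add_node(make_entity("T2", "Gene", sent, 2))
        examples = generate_edge_examples(g, sent, "d", ren_schema)
        assert len(examples) == 1

    def test_schema_filter_removes_only_negatives(self, ge_schema,
                                                  small_corpus):
        # on synthetic gold, no gold-positive pair is filtered out
        from eventex.pipeline import prepare_documents
        data = prepare_documents(small_corpus.splits["train"][:10], ge_schema)
        for d in data:
            for sent, mg in zip(d.doc.sentences, d.merged_graphs):
                candidates = {(e.provenance[2], e.provenance[3])
                              for e in generate_edge_examples(
                                  mg, sent, d.doc.doc_id, ge_schema)}
                for edge in mg.edges:
                    key = (edge.source, edge.target)
                    assert key in candidates, \
                        f"gold edge {edge} missing from candidates"


class TestModalityExamples:
    def test_independent_binary_dimensions(self, ge_schema):
        sent = make_sentence("ABC1 is not expressed",
                             deps=[(3, 0, "nsubjpass"), (3, 1, "auxpass"),
                                   (3, 2, "neg")])
        p = make_entity("T1", "Protein", sent, 0)
        t = make_entity("T2", "Gene_expression", sent, 3, given=False)
        ev = make_event("E1", "Gene_expression", t, ("Theme", p),
                        negation=True, speculation=True)
        neg = generate_modality_examples([ev], sent, "d", "Negation", [p])
        spec = generate_modality_examples([ev], sent, "d", "Speculation", [p])
        assert neg[0].label == "Negation"
        assert spec[0].label == "Speculation"

    def test_triggerless_events_skipped(self, ren_schema):
        sent = make_sentence("yabA renamed orf12")
        a = make_entity("T1", "Gene", sent, 0)
        b = make_entity("T2", "Gene", sent, 2)
        rel = make_event("R1", "Renaming", None, ("Former", a), ("New", b))
        assert generate_modality_examples([rel], sent, "d", "Negation",
                                          []) == []


# ---------------------------------------------------------------------------
# EPI reverse-type rule: 50-case suite covering every branch, checked
# against an independently hand-written expectation table.

EPI_RULE_CASES = [
    # "de"-prefix firing
    ("dephosphorylation", "Phosphorylation", "Dephosphorylation"),
    ("dephosphorylated", "Phosphorylation", "Dephosphorylation"),
    ("Dephosphorylates", "Phosphorylation", "Dephosphorylation"),
    ("DEPHOSPHORYLATION", "Phosphorylation", "Dephosphorylation"),
    ("demethylation", "Methylation", "Demethylation"),
    ("demethylated", "DNA_methylation", "DNA_demethylation"),
    ("deacetylation", "Acetylation", "Deacetylation"),
    ("deacetylase", "Acetylation", "Deacetylation"),
    ("deubiquitination", "Ubiquitination", "Deubiquitination"),
    ("deubiquitinating", "Ubiquitination", "Deubiquitination"),
    ("deglycosylation", "Glycosylation", "Deglycosylation"),
    ("dehydroxylation", "Hydroxylation", "Dehydroxylation"),
    ("degrades", "Methylation", "Demethylation"),   # any "de" prefix fires
    ("detaches", "Acetylation", "Deacetylation"),
    # "remov" substring
    ("removal", "Methylation", "Demethylation"),
    ("removed", "Acetylation", "Deacetylation"),
    ("removes", "Phosphorylation", "Dephosphorylation"),
    ("removing", "Ubiquitination", "Deubiquitination"),
    ("Removal", "Glycosylation", "Deglycosylation"),
    ("group-removal", "Methylation", "Demethylation"),
    # "loss" substring
    ("loss", "Methylation", "Demethylation"),
    ("losses", "Acetylation", "Deacetylation"),
    ("Loss", "DNA_methylation", "DNA_demethylation"),
    ("methyl-loss", "Methylation", "Demethylation"),
    ("lossof", "Phosphorylation", "Dephosphorylation"),
    # "erasure" substring
    ("erasure", "Methylation", "Demethylation"),
    ("Erasure", "Acetylation", "Deacetylation"),
    ("mark-erasure", "Methylation", "Demethylation"),
    ("erasures", "Ubiquitination", "Deubiquitination"),
    ("erasure-like", "Glycosylation", "Deglycosylation"),
    # non-firing forward cases
    ("phosphorylation", "Phosphorylation", "Phosphorylation"),
    ("phosphorylates", "Phosphorylation", "Phosphorylation"),
    ("methylation", "Methylation", "Methylation"),
    ("methylated", "DNA_methylation", "DNA_methylation"),
    ("acetylation", "Acetylation", "Acetylation"),
    ("acetylates", "Acetylation", "Acetylation"),
    ("ubiquitination", "Ubiquitination", "Ubiquitination"),
    ("ubiquitinated", "Ubiquitination", "Ubiquitination"),
    ("glycosylation", "Glycosylation", "Glycosylation"),
    ("hydroxylation", "Hydroxylation", "Hydroxylation"),
    ("adds", "Methylation", "Methylation"),
    ("attaches", "Acetylation", "Acetylation"),
    ("conjugation", "Ubiquitination", "Ubiquitination"),
    ("transfer", "Phosphorylation", "Phosphorylation"),
    # tricky: "de" inside but not prefix, "los"/"eras" incomplete
    ("modified", "Methylation", "Methylation"),
    ("guided", "Acetylation", "Acetylation"),
    ("lost", "Methylation", "Methylation"),
    ("closure", "Phosphorylation", "Phosphorylation"),
    ("erase", "Methylation", "Methylation"),
    # non-reversible type never flips
    ("dephosphorylation", "Catalysis", "Catalysis"),
]


def test_epi_rule_case_count_covers_suite():
    assert len(EPI_RULE_CASES) == 50


@pytest.mark.parametrize("text,forward,expected", EPI_RULE_CASES)
def test_epi_reverse_rule_agrees_with_oracle(text, forward, expected):
    assert epi_reverse_rule(text, forward, EPI_REVERSE_TYPES) == expected


# ---------------------------------------------------------------------------
# bacterium-name span extension: 30 constructed token sequences with a
# hand-built expectation table (head index -> expected token span).

LEXICON = {"bacillus", "subtilis", "escherichia", "coli", "mycobacterium",
           "tuberculosis", "b.", "e.", "listeria", "monocytogenes"}

BB_CASES = [
    # (tokens, head index, expected (first, last) token of span)
    (["B.", "subtilis"], 1, (0, 1)),
    (["B.", "subtilis", "grows"], 1, (0, 1)),
    (["the", "B.", "subtilis", "grows"], 2, (1, 2)),
    (["E.", "coli"], 1, (0, 1)),
    (["Escherichia", "coli"], 1, (0, 1)),
    (["Escherichia", "coli", "K12"], 1, (0, 1)),
    (["Bacillus", "subtilis", "strain", "168"], 1, (0, 2)),
    (["Mycoplasma"], 0, (0, 0)),                     # suffix "plasma"
    (["Agrobacterium"], 0, (0, 0)),                  # suffix "bacter(ium)"
    (["Streptococcus"], 0, (0, 0)),                  # suffix "coccus"
    (["Salmonella"], 0, (0, 0)),                     # suffix "ella"
    (["Pseudomonas"], 0, (0, 0)),                    # suffix "monas"
    (["Vibrio"], 0, (0, 0)),
    (["cells"], 0, (0, 0)),
    (["the", "bacterium"], 1, (1, 1)),
    (["unknown", "word", "subtilis"], 2, (2, 2)),
    (["Listeria", "monocytogenes", "infects"], 0, (0, 1)),
    (["Mycobacterium", "tuberculosis", "complex"], 0, (0, 2)),
    (["wild", "type", "coli"], 2, (2, 2)),           # neighbours unknown
    (["subsp.", "subtilis"], 1, (0, 1)),
    (["Bacillus", "subtilis", "and", "others"], 0, (0, 1)),
    (["grows", "subtilis", "slowly"], 1, (1, 1)),
    (["B.", "subtilis", "subsp.", "spizizenii"], 1, (0, 3)),  # "ii" suffix
    (["serovar", "Typhimurium"], 1, (0, 1)),         # "um" suffix + rule word
    (["strain", "168"], 0, (0, 0)),
    (["Thermus", "aquaticus"], 0, (0, 1)),           # "us" suffixes
    (["Helicobacter", "pylori"], 0, (0, 0)),         # pylori not known
    (["candidatus", "Liberibacter"], 1, (0, 1)),
    (["the", "E.", "coli", "strain", "DH5"], 2, (1, 3)),
    (["Spirillum"], 0, (0, 0)),
]


def test_bb_case_count_covers_suite():
    assert len(BB_CASES) == 30


@pytest.mark.parametrize("tokens,head,expected", BB_CASES)
def test_bb_extend_span_matches_expectation_table(tokens, head, expected):
    sent = make_sentence(" ".join(tokens))
    lo, hi = expected
    want = (sent.tokens[lo].char_start, sent.tokens[hi].char_end)
    assert bb_extend_span(head, sent, LEXICON) == want
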