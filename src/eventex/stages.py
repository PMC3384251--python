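"""Example generation and post-processing for the detection stages.

Trigger detection classifies every token (outside given entities) as
negative or as one of the trigger classes, with overlapping triggers
encoded as merged classes that are split after prediction. Edge detection
classifies directed node pairs filtered by the task schema. Modality
detection makes two independent binary decisions per triggered event.
Task-specific rule systems: reverse-event type recovery for
post-translational-modification tasks and bacterium-name span extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from eventex.features import (
    Lexicons,
    SparseExample,
    dependency_chain_features,
    node_pair_features,
    pair_external_features,
    path_ngram_features,
    sentence_features,
    token_external_features,
    token_features,
)
from eventex.graph import EntityNode, EventGraph, Event
from eventex.learning import NEGATIVE
from eventex.schema import TaskSchema
from eventex.standoff import Sentence

MERGED_SEPARATOR = "---"


def merge_class_label(components: list[str]) -> str:
    """Render overlapping classes as one merged label (sorted, separator-
    joined) so that splitting recovers the components exactly."""
    uniq = sorted(set(components))
    if not uniq:
        return NEGATIVE
    return MERGED_SEPARATOR.join(uniq)


def split_class_label(label: str) -> list[str]:
    if label == NEGATIVE:
        return []
    return label.split(MERGED_SEPARATOR)


# ---------------------------------------------------------------------------
# trigger detection

def _inside_given(token, given_nodes) -> bool:
    return any(s <= token.char_start and token.char_end <= e
               for node in given_nodes for s, e in node.char_spans)


def trigger_example_features(token, sentence: Sentence, given_nodes,
                             lexicons: Lexicons | None) -> dict[str, float]:
    f = token_features(token, sentence)
    f.update(sentence_features(sentence, given_nodes))
    f.update(dependency_chain_features(token, sentence))
    f.update(token_external_features(token, sentence, lexicons))
    return f


def generate_trigger_examples(sentence: Sentence, doc_id: str,
                              gold_graph: EventGraph | None,
                              given_nodes: list[EntityNode],
                              lexicons: Lexicons | None = None
                              ) -> list[SparseExample]:
    """One example per candidate token; the gold label is the merged class
    of all gold trigger nodes headed at that token. Features are identical
    whether or not gold labels exist."""
    examples = []
    gold_by_head: dict[int, list[str]] = {}
    if gold_graph is not None:
        for node in gold_graph.nodes.values():
            if not node.given:
                gold_by_head.setdefault(node.head_token, []).append(node.type)
    for token in sentence.tokens:
        if _inside_given(token, given_nodes):
            continue
        label = merge_class_label(gold_by_head.get(token.index, []))
        examples.append(SparseExample(
            example_id=f"{doc_id}.s{sentence.index}.t{token.index}",
            features=trigger_example_features(token, sentence, given_nodes,
                                              lexicons),
            label=label,
            provenance=(doc_id, sentence.index, token.index)))
    return examples


def split_merged_predictions(predictions: list[tuple[Sentence, int, str, float]]
                             ) -> list[EntityNode]:
    """Turn per-token predictions into trigger nodes, one node per
    component class of a merged label."""
    nodes: list[EntityNode] = []
    for sentence, token_index, label, confidence in predictions:
        token = sentence.tokens[token_index]
        for comp in split_class_label(label):
            nodes.append(EntityNode(
                node_id=f"trig.s{sentence.index}.t{token_index}.{comp}",
                type=comp, head_token=token_index,
                char_spans=[(token.char_start, token.char_end)],
                given=False, text=token.text,
                sentence_index=sentence.index, confidence=confidence))
    return nodes


# ---------------------------------------------------------------------------
# edge detection

def edge_example_features(node_a: EntityNode, node_b: EntityNode,
                          sentence: Sentence, schema: TaskSchema,
                          lexicons: Lexicons | None) -> dict[str, float]:
    f = path_ngram_features(node_a, node_b, sentence)
    f.update(node_pair_features(node_a, node_b, schema))
    f.update(pair_external_features(node_a, node_b, lexicons))
    if 0 <= node_a.head_token < len(sentence.tokens):
        f.update(token_features(sentence.tokens[node_a.head_token],
                                sentence, prefix="srcTok_"))
    if 0 <= node_b.head_token < len(sentence.tokens):
        f.update(token_features(sentence.tokens[node_b.head_token],
                                sentence, prefix="dstTok_"))
    return f


def generate_edge_examples(graph: EventGraph, sentence: Sentence,
                           doc_id: str, schema: TaskSchema,
                           lexicons: Lexicons | None = None,
                           labeled: bool = True) -> list[SparseExample]:
    """One example per directed node pair (per unordered pair for undirected
    relation tasks), filtered by the schema's valid argument-type rules.
    The gold label is the merged class of the graph's edge types on that
    directed pair, when ``labeled``."""
    examples = []
    gold: dict[tuple[str, str], list[str]] = {}
    if labeled:
        for e in graph.edges:
            gold.setdefault((e.source, e.target), []).append(e.type)
            if not e.directed:
                gold.setdefault((e.target, e.source), []).append(e.type)

    nodes = sorted(graph.nodes.values(), key=lambda n: (n.char_spans[0], n.type))
    undirected_only = bool(schema.undirected_relation_types) \
        and not schema.event_types
    for i, a in enumerate(nodes):
        for j, b in enumerate(nodes):
            if i == j:
                continue
            if undirected_only and j < i:
                continue
            if not schema.valid_edge_pair(a.type, b.type):
                continue
            label = merge_class_label(gold.get((a.node_id, b.node_id), [])) \
                if labeled else NEGATIVE
            examples.append(SparseExample(
                example_id=f"{doc_id}.s{sentence.index}.e."
                           f"{a.node_id}>{b.node_id}",
                features=edge_example_features(a, b, sentence, schema, lexicons),
                label=label,
                provenance=(doc_id, sentence.index, a.node_id, b.node_id)))
    return examples


# ---------------------------------------------------------------------------
# modality detection

def modality_example_features(event: Event, sentence: Sentence,
                              given_nodes, lexicons: Lexicons | None
                              ) -> dict[str, float]:
    token = sentence.tokens[event.trigger.head_token]
    f = trigger_example_features(token, sentence, given_nodes, lexicons)
    f[f"trigType={event.type}"] = 1.0
    return f


def generate_modality_examples(events: list[Event], sentence: Sentence,
                               doc_id: str, dimension: str,
                               given_nodes, lexicons: Lexicons | None = None,
                               labeled: bool = True) -> list[SparseExample]:
    """Binary examples (one per triggered event) for one modality dimension
    ('Negation' or 'Speculation'); triggerless events are skipped."""
    examples = []
    for k, ev in enumerate(events):
        if ev.trigger is None:
            continue
        flag = ev.negation if dimension == "Negation" else ev.speculation
        label = dimension if (labeled and flag) else NEGATIVE
        examples.append(SparseExample(
            example_id=f"{doc_id}.s{sentence.index}.m{dimension}.{k}",
            features=modality_example_features(ev, sentence, given_nodes,
                                               lexicons),
            label=label,
            provenance=(doc_id, sentence.index, ev.event_id, dimension)))
    return examples


# ---------------------------------------------------------------------------
# EPI reverse-event rule

REVERSE_TRIGGER_SUBSTRINGS = ("remov", "loss", "erasure")

# forward modification type -> its reverse type
EPI_REVERSE_TYPES = {
    "Phosphorylation": "Dephosphorylation",
    "Hydroxylation": "Dehydroxylation",
    "Ubiquitination": "Deubiquitination",
    "DNA_methylation": "DNA_demethylation",
    "Glycosylation": "Deglycosylation",
    "Acetylation": "Deacetylation",
    "Methylation": "Demethylation",
}


def epi_reverse_rule(trigger_text: str, forward_type: str,
                     reverse_map: dict[str, str] = EPI_REVERSE_TYPES) -> str:
    """Recover reverse event types merged into their forward type.

    The reverse type is returned when the trigger text starts with "de"
    (case-insensitive) or contains one of the strings "remov", "loss" or
    "erasure"; otherwise the forward type stands."""
    low = trigger_text.lower()
    if forward_type not in reverse_map:
        return forward_type
    if low.startswith("de") or any(s in low for s in REVERSE_TRIGGER_SUBSTRINGS):
        return reverse_map[forward_type]
    return forward_type


# ---------------------------------------------------------------------------
# bacterium-name span extension

# Partial default rule lists: common latinate bacterium-name suffixes and
# other substrings that occur inside multi-token bacterium names. Editable
# via configuration.
DEFAULT_BACTERIUM_SUFFIXES = (
    "um", "us", "is", "ans", "ens", "ii", "ae", "bacter", "bacteria",
    "bacterium", "plasma", "coccus", "cocci", "bacillus", "ella",
    "monas", "myces", "spira", "spirillum", "vibrio", "philus",
)
DEFAULT_BACTERIUM_SUBSTRINGS = (
    "strain", "strains", "subspecies", "subsp", "spp", "sp", "str",
    "serovar", "serotype", "biovar", "pathovar", "phage", "candidatus",
    "group", "complex", "cluster", "isolate",
)


def _bacterium_token(text: str, lexicon: set[str],
                     suffix_rules, substring_rules) -> bool:
    low = text.lower().strip(".")
    if not low:
        return False
    if low in lexicon or text.lower() in lexicon:
        return True
    if any(low.endswith(suf) for suf in suffix_rules):
        return True
    if any(sub in low for sub in substring_rules):
        return True
    # single-letter genus abbreviations such as "B."
    if len(low) == 1 and text.endswith(".") and text[0].isupper():
        return True
    return False


def bb_extend_span(head_token: int, sentence: Sentence,
                   lexicon: set[str],
                   suffix_rules=DEFAULT_BACTERIUM_SUFFIXES,
                   substring_rules=DEFAULT_BACTERIUM_SUBSTRINGS
                   ) -> tuple[int, int]:
    """Extend a predicted Bacterium trigger token to the full name span.

    Starting from the head token, the span grows forwards and backwards as
    long as each encountered token is a known bacterium-name substring
    (lexicon lookup, suffix rules or other substring rules)."""
    tokens = sentence.tokens
    lo = hi = head_token
    while lo - 1 >= 0 and _bacterium_token(tokens[lo - 1].text, lexicon,
                                           suffix_rules, substring_rules):
        lo -= 1
    while hi + 1 < len(tokens) and _bacterium_token(tokens[hi + 1].text, lexicon,
                                                    suffix_rules, substring_rules):
        hi += 1
    return (tokens[lo].char_start, tokens[hi].char_end)
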