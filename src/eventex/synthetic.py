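"""Synthetic corpus generation.

Produces documents with text, deterministic rule-built dependency parses
and gold standoff annotation exhibiting the structural phenomena the
pipeline must learn: nested events (regulations over events), entity
equivalences (parenthesized aliases), merged triggers (one token heading
two event types), intersentence events, negation/speculation cues, and
trigger words used in a non-event sense (noise). Sentences are short
protein-interaction statements over an invented gene-symbol pool; parses
are synthesized by rule (the verb is the root, arguments attach by
nsubj/dobj-style relations), which is sufficient for the dependency-path
features. Everything is reproducible from the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from eventex.standoff import Document, read_document, read_parse
from eventex.stemming import stem as porter_stem

DEFAULT_PROTEIN_POOL = [
    "ABX1", "BRC4", "CDK9L", "DRX2", "EFT5", "FZD11", "GRK3", "HOX7A",
    "IKKE2", "JAK5", "KLF12", "LMO4B", "MEK6", "NFA9", "OCT3L", "PLK8",
    "QSOX3", "RAB27X", "SMAD9", "TRAF8", "UBX5", "VAV2L", "WNT13", "XPO6",
    "YAP3", "ZEB4", "ARF8L", "BTK2", "CREB7", "DUSP9", "ELK4", "FOXQ2",
    "GATA8", "HIF3B", "IRF9L", "JUNB2", "KRAS5", "LYN3", "MYC8L", "NOTCH5",
]

DEFAULT_TRIGGER_LEXICON = {
    "Gene_expression": {"passive": ["expressed", "produced", "synthesized",
                                    "overexpressed"],
                        "nominal": ["expression", "production"]},
    "Phosphorylation": {"passive": ["phosphorylated", "hyperphosphorylated"],
                        "nominal": ["phosphorylation"]},
    "Binding": {"active": ["binds", "contacts", "recruits"]},
    "Regulation": {"active": ["regulates", "modulates", "controls"]},
    "Positive_regulation": {"active": ["activates", "stimulates",
                                       "upregulates"],
                            "merged": ["induces", "triggers"]},
    "Negative_regulation": {"active": ["inhibits", "suppresses",
                                       "downregulates"]},
}

SIMPLE_PASSIVE_TYPES = ("Gene_expression", "Phosphorylation")
REGULATION_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")


@dataclass
class CorpusSpec:
    """Generation parameters; the defaults define the standard study
    conditions used throughout the test suite.

    Phenomenon rates loosely emulate the event-annotated corpora this
    format comes from: roughly a third of events nested, mid-single-digit
    percentages of equivalence-affected and intersentence events, ~2%
    merged triggers and ~13% negated or speculated events.
    """
    n_train: int = 500
    n_devel: int = 100
    n_test: int = 100
    sentences_per_doc: tuple[int, int] = (3, 6)
    trigger_lexicon: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_TRIGGER_LEXICON.items()})
    protein_pool: list[str] = field(
        default_factory=lambda: list(DEFAULT_PROTEIN_POOL))
    nesting_prob: float = 0.35
    equiv_prob: float = 0.07
    intersentence_prob: float = 0.05
    merged_trigger_prob: float = 0.02
    negation_prob: float = 0.07
    speculation_prob: float = 0.06
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("nesting_prob", "equiv_prob", "intersentence_prob",
                     "merged_trigger_prob", "negation_prob",
                     "speculation_prob", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for etype, forms in self.trigger_lexicon.items():
            if not any(forms.values()):
                raise ValueError(f"empty trigger lexicon for {etype}")


# ---------------------------------------------------------------------------
# sentence plans

@dataclass
class PlannedEvent:
    type: str
    trigger_tok: Optional[int]            # local token index
    args: list[tuple[str, tuple]]         # (role, ('ent', i) | ('ev', k))
    negation: bool = False
    speculation: bool = False


@dataclass
class SentencePlan:
    tokens: list[tuple[str, str]]                 # (text, POS)
    deps: list[tuple[int, int, str]]              # (governor, dependent, type)
    entities: list[tuple[int, str]] = field(default_factory=list)
    events: list[PlannedEvent] = field(default_factory=list)
    equiv_pairs: list[tuple[int, int]] = field(default_factory=list)
    flags: set = field(default_factory=set)       # bookkeeping


def _passive_simple(rng, spec, etype, negated=False, speculated=False,
                    with_equiv=False) -> SentencePlan:
    prot = rng.choice(spec.protein_pool)
    word = rng.choice(spec.trigger_lexicon[etype]["passive"])
    toks: list[tuple[str, str]] = [(prot, "NNP")]
    deps: list[tuple[int, int, str]] = []
    entities = [(0, "Protein")]
    equiv_pairs = []
    if with_equiv:
        alias = prot.capitalize() + "p"
        toks += [("(", "-LRB-"), (alias, "NNP"), (")", "-RRB-")]
        entities.append((2, "Protein"))
        deps += [(0, 1, "punct"), (0, 2, "appos"), (0, 3, "punct")]
        equiv_pairs.append((0, 1))
    base = len(toks)
    if speculated:
        toks += [("may", "MD"), ("be", "VB"), (word, "VBN"), (".", ".")]
        w = base + 2
        deps += [(w, base, "aux"), (w, base + 1, "auxpass"), (w, 0, "nsubjpass"),
                 (w, base + 3, "punct")]
    elif negated:
        toks += [("is", "VBZ"), ("not", "RB"), (word, "VBN"), (".", ".")]
        w = base + 2
        deps += [(w, base, "auxpass"), (w, base + 1, "neg"), (w, 0, "nsubjpass"),
                 (w, base + 3, "punct")]
    else:
        toks += [("is", "VBZ"), (word, "VBN"), (".", ".")]
        w = base + 1
        deps += [(w, base, "auxpass"), (w, 0, "nsubjpass"), (w, base + 2, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps, entities=entities,
                        equiv_pairs=equiv_pairs)
    plan.events.append(PlannedEvent(etype, w, [("Theme", ("ent", 0))],
                                    negation=negated, speculation=speculated))
    if with_equiv:
        plan.flags.add("equiv")
    if negated:
        plan.flags.add("negation")
    if speculated:
        plan.flags.add("speculation")
    return plan


def _binding(rng, spec) -> SentencePlan:
    p1, p2 = rng.sample(spec.protein_pool, 2)
    word = rng.choice(spec.trigger_lexicon["Binding"]["active"])
    toks = [(p1, "NNP"), (word, "VBZ"), (p2, "NNP"), (".", ".")]
    deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps,
                        entities=[(0, "Protein"), (2, "Protein")])
    plan.events.append(PlannedEvent("Binding", 1,
                                    [("Theme", ("ent", 0)),
                                     ("Theme", ("ent", 1))]))
    return plan


def _regulation(rng, spec, rtype) -> SentencePlan:
    p1, p2 = rng.sample(spec.protein_pool, 2)
    word = rng.choice(spec.trigger_lexicon[rtype]["active"])
    toks = [(p1, "NNP"), (word, "VBZ"), (p2, "NNP"), (".", ".")]
    deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps,
                        entities=[(0, "Protein"), (2, "Protein")])
    plan.events.append(PlannedEvent(rtype, 1, [("Theme", ("ent", 1)),
                                               ("Cause", ("ent", 0))]))
    return plan


def _nested(rng, spec, rtype, inner_type) -> SentencePlan:
    p1, p2 = rng.sample(spec.protein_pool, 2)
    word = rng.choice(spec.trigger_lexicon[rtype]["active"])
    noun = rng.choice(spec.trigger_lexicon[inner_type]["nominal"])
    toks = [(p1, "NNP"), (word, "VBZ"), ("the", "DT"), (noun, "NN"),
            ("of", "IN"), (p2, "NNP"), (".", ".")]
    deps = [(1, 0, "nsubj"), (1, 3, "dobj"), (3, 2, "det"),
            (3, 4, "prep"), (3, 5, "prep_of"), (1, 6, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps,
                        entities=[(0, "Protein"), (5, "Protein")])
    plan.events.append(PlannedEvent(inner_type, 3, [("Theme", ("ent", 1))]))
    plan.events.append(PlannedEvent(rtype, 1, [("Theme", ("ev", 0)),
                                               ("Cause", ("ent", 0))]))
    plan.flags.add("nesting")
    return plan


def _merged_trigger(rng, spec) -> SentencePlan:
    """One token heading both an expression event and the regulation of it
    — an overlapping-trigger (merged class) case."""
    p1, p2 = rng.sample(spec.protein_pool, 2)
    word = rng.choice(spec.trigger_lexicon["Positive_regulation"]["merged"])
    toks = [(p1, "NNP"), (word, "VBZ"), (p2, "NNP"), (".", ".")]
    deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps,
                        entities=[(0, "Protein"), (2, "Protein")])
    plan.events.append(PlannedEvent("Gene_expression", 1,
                                    [("Theme", ("ent", 1))]))
    plan.events.append(PlannedEvent("Positive_regulation", 1,
                                    [("Theme", ("ev", 0)),
                                     ("Cause", ("ent", 0))]))
    plan.flags.update(("merged", "nesting"))
    return plan


def _noise(rng, spec) -> SentencePlan:
    """A trigger word used in a non-event sense: no entities, no events."""
    form = rng.choice(("passive", "active", "nominal"))
    if form == "passive":
        etype = rng.choice(SIMPLE_PASSIVE_TYPES)
        word = rng.choice(spec.trigger_lexicon[etype]["passive"])
        toks = [("It", "PRP"), ("is", "VBZ"), (word, "VBN"), (".", ".")]
        deps = [(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "punct")]
    elif form == "active":
        rtype = rng.choice(REGULATION_TYPES + ("Binding",))
        word = rng.choice(spec.trigger_lexicon[rtype]["active"])
        toks = [("This", "DT"), (word, "VBZ"), ("nothing", "NN"), (".", ".")]
        deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")]
    else:
        etype = rng.choice(SIMPLE_PASSIVE_TYPES)
        noun = rng.choice(spec.trigger_lexicon[etype]["nominal"])
        toks = [("The", "DT"), (noun, "NN"), ("was", "VBD"),
                ("observed", "VBN"), (".", ".")]
        deps = [(3, 1, "nsubjpass"), (1, 0, "det"), (3, 2, "auxpass"),
                (3, 4, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps)
    plan.flags.add("noise")
    return plan


def _intersentence_head(rng, spec, rtype) -> SentencePlan:
    p1 = rng.choice(spec.protein_pool)
    word = rng.choice(spec.trigger_lexicon[rtype]["active"])
    toks = [(p1, "NNP"), (word, "VBZ"), ("this", "DT"), (".", ".")]
    deps = [(1, 0, "nsubj"), (1, 2, "dobj"), (1, 3, "punct")]
    plan = SentencePlan(tokens=toks, deps=deps, entities=[(0, "Protein")])
    plan.flags.add("intersentence-head")
    return plan


# ---------------------------------------------------------------------------
# document assembly

@dataclass
class GeneratedDoc:
    document: Optional[Document]
    txt: str
    a1: str
    a2: str
    conll: str
    ledger: dict


def _plan_document(rng, spec: CorpusSpec) -> tuple[list[SentencePlan], list]:
    n_sentences = rng.randint(*spec.sentences_per_doc)
    plans: list[SentencePlan] = []
    cross_events = []   # (rtype, head_sent_idx, theme: (sent_idx, ev_idx))
    i = 0
    while i < n_sentences:
        r = rng.random()
        if r < spec.noise_rate:
            plans.append(_noise(rng, spec))
            i += 1
            continue
        if r < spec.noise_rate + spec.intersentence_prob and i + 2 <= n_sentences:
            rtype = rng.choice(REGULATION_TYPES)
            head = _intersentence_head(rng, spec, rtype)
            body = _passive_simple(rng, spec, rng.choice(SIMPLE_PASSIVE_TYPES))
            plans.append(head)
            plans.append(body)
            cross_events.append((rtype, len(plans) - 2,
                                 (len(plans) - 1, 0)))
            i += 2
            continue
        if rng.random() < spec.merged_trigger_prob:
            plans.append(_merged_trigger(rng, spec))
        elif rng.random() < spec.nesting_prob:
            rtype = rng.choice(REGULATION_TYPES)
            inner = rng.choice(SIMPLE_PASSIVE_TYPES)
            plans.append(_nested(rng, spec, rtype, inner))
        else:
            kind = rng.choice(("passive", "passive", "binding", "regulation"))
            if kind == "passive":
                etype = rng.choice(SIMPLE_PASSIVE_TYPES)
                with_equiv = rng.random() < spec.equiv_prob
                negated = (not with_equiv) and rng.random() < spec.negation_prob
                speculated = (not with_equiv and not negated
                              and rng.random() < spec.speculation_prob)
                plans.append(_passive_simple(rng, spec, etype, negated,
                                             speculated, with_equiv))
            elif kind == "binding":
                plans.append(_binding(rng, spec))
            else:
                plans.append(_regulation(rng, spec, rng.choice(REGULATION_TYPES)))
        i += 1
    return plans, cross_events


def _render_document(doc_id: str, plans: list[SentencePlan],
                     cross_events: list) -> GeneratedDoc:
    # text and token offsets
    sent_texts = []
    token_offsets: list[list[tuple[int, int]]] = []
    offset = 0
    for plan in plans:
        parts = []
        offs = []
        pos = offset
        for k, (text, _) in enumerate(plan.tokens):
            if k > 0:
                pos += 1   # single space
            offs.append((pos, pos + len(text)))
            parts.append(text)
            pos += len(text)
        sent_texts.append(" ".join(parts))
        token_offsets.append(offs)
        offset = pos + 1   # newline
    text = "\n".join(sent_texts) + "\n"

    a1_lines: list[str] = []
    a2_lines: list[str] = []
    ent_ids: dict[tuple[int, int], str] = {}   # (sent, local ent idx) -> T id
    next_t = 1
    for si, plan in enumerate(plans):
        for li, (tok_idx, etype) in enumerate(plan.entities):
            s, e = token_offsets[si][tok_idx]
            tid = f"T{next_t}"
            next_t += 1
            a1_lines.append(f"{tid}\t{etype} {s} {e}\t{plan.tokens[tok_idx][0]}")
            ent_ids[(si, li)] = tid

    # one trigger T line per (token, event type): overlapping events of
    # different types on one token keep distinct typed triggers
    trig_ids: dict[tuple[int, int, str], str] = {}
    for si, plan in enumerate(plans):
        for ev in plan.events:
            key = (si, ev.trigger_tok, ev.type)
            if key not in trig_ids:
                s, e = token_offsets[si][ev.trigger_tok]
                tid = f"T{next_t}"
                next_t += 1
                a2_lines.append(
                    f"{tid}\t{ev.type} {s} {e}\t{plan.tokens[ev.trigger_tok][0]}")
                trig_ids[key] = tid
    # cross-sentence triggers
    cross_trig: dict[int, str] = {}
    for ci, (rtype, head_si, _) in enumerate(cross_events):
        plan = plans[head_si]
        tok = 1   # the verb in the intersentence-head template
        s, e = token_offsets[head_si][tok]
        tid = f"T{next_t}"
        next_t += 1
        a2_lines.append(f"{tid}\t{rtype} {s} {e}\t{plan.tokens[tok][0]}")
        cross_trig[ci] = tid

    # E lines (inner events first: plan order already lists them first)
    ev_ids: dict[tuple[int, int], str] = {}
    next_e = 1
    mod_lines: list[str] = []
    next_m = 1

    def ref(si, target):
        kind, idx = target
        if kind == "ent":
            return ent_ids[(si, idx)]
        return ev_ids[(si, idx)]

    for si, plan in enumerate(plans):
        for k, ev in enumerate(plan.events):
            eid = f"E{next_e}"
            next_e += 1
            ev_ids[(si, k)] = eid
            role_counts: dict[str, int] = {}
            parts = [f"{ev.type}:{trig_ids[(si, ev.trigger_tok, ev.type)]}"]
            for role, target in ev.args:
                n = role_counts.get(role, 0)
                role_counts[role] = n + 1
                label = role if n == 0 else f"{role}{n + 1}"
                parts.append(f"{label}:{ref(si, target)}")
            a2_lines.append(f"{eid}\t" + " ".join(parts))
            if ev.negation:
                mod_lines.append(f"M{next_m}\tNegation {eid}")
                next_m += 1
            if ev.speculation:
                mod_lines.append(f"M{next_m}\tSpeculation {eid}")
                next_m += 1
    for ci, (rtype, head_si, (body_si, body_ev)) in enumerate(cross_events):
        eid = f"E{next_e}"
        next_e += 1
        cause = ent_ids[(head_si, 0)]
        a2_lines.append(f"{eid}\t{rtype}:{cross_trig[ci]} "
                        f"Theme:{ev_ids[(body_si, body_ev)]} Cause:{cause}")
    a2_lines.extend(mod_lines)
    for si, plan in enumerate(plans):
        for (a, b) in plan.equiv_pairs:
            a2_lines.append(f"*\tEquiv {ent_ids[(si, a)]} {ent_ids[(si, b)]}")

    # parse blocks
    conll_blocks = []
    for plan in plans:
        governor_of = {d: (g, t) for g, d, t in plan.deps}
        rows = []
        for k, (tok, pos) in enumerate(plan.tokens):
            if k in governor_of:
                head, dtype = governor_of[k]
                rows.append(f"{k + 1}\t{tok}\t{porter_stem(tok)}\t{pos}"
                            f"\t{head + 1}\t{dtype}")
            else:
                rows.append(f"{k + 1}\t{tok}\t{porter_stem(tok)}\t{pos}\t0\troot")
        conll_blocks.append("\n".join(rows))
    conll = "\n\n".join(conll_blocks) + "\n"

    n_events = next_e - 1
    ledger = {
        "sentences": len(plans),
        "events": n_events,
        "nesting_events": sum(1 for p in plans for ev in p.events
                              if any(t[0] == "ev" for _, t in ev.args))
        + len(cross_events),
        "equiv_affected_events": sum(
            len(p.events) for p in plans if "equiv" in p.flags),
        "intersentence_events": len(cross_events),
        "negspec_events": sum(1 for p in plans for ev in p.events
                              if ev.negation or ev.speculation),
        "noise_sentences": sum(1 for p in plans if "noise" in p.flags),
        "merged_trigger_tokens": sum(1 for p in plans if "merged" in p.flags),
    }
    return GeneratedDoc(document=None, txt=text,
                        a1="\n".join(a1_lines) + ("\n" if a1_lines else ""),
                        a2="\n".join(a2_lines) + ("\n" if a2_lines else ""),
                        conll=conll, ledger=ledger)


def generate_document(doc_id: str, rng: random.Random,
                      spec: CorpusSpec) -> GeneratedDoc:
    plans, cross = _plan_document(rng, spec)
    return _render_document(doc_id, plans, cross)


@dataclass
class GeneratedCorpus:
    root: Optional[Path]
    splits: dict[str, list[Document]]
    ledger: dict[str, dict]


def _materialize(doc_id: str, gen: GeneratedDoc,
                 outdir: Optional[Path]) -> Document:
    if outdir is not None:
        (outdir / f"{doc_id}.txt").write_text(gen.txt, encoding="utf-8")
        (outdir / f"{doc_id}.a1").write_text(gen.a1, encoding="utf-8")
        (outdir / f"{doc_id}.a2").write_text(gen.a2, encoding="utf-8")
        (outdir / f"{doc_id}.conll").write_text(gen.conll, encoding="utf-8")
        doc = read_document(outdir / f"{doc_id}.txt", outdir / f"{doc_id}.a1",
                            outdir / f"{doc_id}.a2")
        return read_parse(outdir / f"{doc_id}.conll", doc)
    import tempfile
    with tempfile.TemporaryDirectory() as td:
        return _materialize(doc_id, gen, Path(td))


def generate(spec: CorpusSpec, outdir=None) -> GeneratedCorpus:
    """Generate a train/devel/test corpus; files are written under
    ``outdir`` (if given) and parsed Documents returned either way."""
    root = Path(outdir) if outdir is not None else None
    splits: dict[str, list[Document]] = {}
    ledgers: dict[str, dict] = {}
    for split, n_docs, offset in (("train", spec.n_train, 0),
                                  ("devel", spec.n_devel, 1),
                                  ("test", spec.n_test, 2)):
        rng = random.Random((spec.seed * 4 + offset) % (2 ** 31))
        split_dir = None
        if root is not None:
            split_dir = root / split
            split_dir.mkdir(parents=True, exist_ok=True)
        docs = []
        totals: dict[str, int] = {}
        for k in range(n_docs):
            doc_id = f"SYN-{split}-{k:04d}"
            gen = generate_document(doc_id, rng, spec)
            for key, v in gen.ledger.items():
                totals[key] = totals.get(key, 0) + v
            docs.append(_materialize(doc_id, gen, split_dir))
        splits[split] = docs
        ledgers[split] = totals
    return GeneratedCorpus(root=root, splits=splits, ledger=ledgers)


def read_corpus_dir(path) -> list[Document]:
    """Read every standoff document (txt/a1/a2/conll) in a directory."""
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        a1 = txt.with_suffix(".a1")
        a2 = txt.with_suffix(".a2")
        doc = read_document(txt, a1 if a1.exists() else None,
                            a2 if a2.exists() else None)
        conll = txt.with_suffix(".conll")
        if conll.exists():
            read_parse(conll, doc)
        docs.append(doc)
    return docs


def corpus_statistics(docs: list[Document]) -> dict:
    """Summary of the corpus-statistics dimensions: sentence and event
    counts plus the percentages of equivalence-affected, nesting,
    intersentence and negated/speculated events."""
    n_sentences = 0
    n_events = 0
    equiv_events = 0
    nesting_events = 0
    intersentence = 0
    negspec = 0
    for doc in docs:
        n_sentences += len(doc.sentences)
        entities = doc.entities()
        equiv_members = {m for s in doc.equiv_sets() for m in s}
        events = {a.line_id: a for a in doc.annotations if a.kind == "event"}
        relations = {a.line_id: a for a in doc.annotations
                     if a.kind == "relation"}
        modified = {a.args[0][1] for a in doc.annotations
                    if a.kind == "modifier" and a.args}

        def sentence_of(tid: str) -> Optional[int]:
            ann = entities.get(tid)
            if ann is None:
                return None
            sent = doc.sentence_at(ann.spans[0][0])
            return sent.index if sent else None

        def event_sentences(eid: str, seen=()) -> set:
            if eid in seen:
                return set()
            ann = events.get(eid) or relations.get(eid)
            if ann is None:
                return set()
            out = set()
            if ann.trigger:
                out.add(sentence_of(ann.trigger))
            for _, target in ann.args:
                if target in entities:
                    out.add(sentence_of(target))
                else:
                    out |= event_sentences(target, seen + (eid,))
            return out

        def references_equiv(eid: str, seen=()) -> bool:
            if eid in seen:
                return False
            ann = events.get(eid) or relations.get(eid)
            if ann is None:
                return False
            for _, target in ann.args:
                if target in equiv_members:
                    return True
                if target not in entities and references_equiv(
                        target, seen + (eid,)):
                    return True
            return False

        for eid, ann in list(events.items()) + list(relations.items()):
            n_events += 1
            if any(t not in entities for _, t in ann.args):
                nesting_events += 1
            if len(event_sentences(eid)) > 1:
                intersentence += 1
            if references_equiv(eid):
                equiv_events += 1
            if eid in modified:
                negspec += 1

    def pct(x):
        return 100.0 * x / n_events if n_events else 0.0

    return {
        "sentences": n_sentences,
        "events": n_events,
        "equiv_events_pct": pct(equiv_events),
        "nesting_events_pct": pct(nesting_events),
        "intersentence_events_pct": pct(intersentence),
        "negspec_events_pct": pct(negspec),
    }
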