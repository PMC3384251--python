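"""Shared-task standoff I/O and dependency-parse attachment.

Reads the three-file standoff representation (``.txt`` text, ``.a1`` given
entities, ``.a2`` events/relations/modifiers/equivalences; tab-separated,
0-based half-open character offsets) into a :class:`Document`, attaches
CoNLL-style dependency parses, and writes predicted events back out as
``.a2`` text.

Sentence segmentation convention: one sentence per non-empty line of the
``.txt`` file. Parse files carry one blank-line-separated block per sentence
with six columns (index, form, stem, POS, head, deprel; head 0 = root).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from eventex.stemming import stem as porter_stem

PUNCT_CHARS = set("/-.,;:()[]{}+'\"")


class StandoffParseError(ValueError):
    pass


class OffsetError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class Token:
    index: int
    text: str
    char_start: int
    char_end: int
    pos: str = ""
    stem: str = ""


@dataclass
class Dependency:
    governor: int
    dependent: int
    dep_type: str


@dataclass
class Sentence:
    index: int
    char_start: int
    char_end: int
    tokens: list[Token] = field(default_factory=list)
    dependencies: list[Dependency] = field(default_factory=list)


@dataclass
class StandoffLine:
    """One annotation record.

    kind is one of ``entity`` (T), ``event`` (E), ``relation`` (R),
    ``modifier`` (M), ``equiv`` (*) or ``other`` (preserved verbatim).
    """

    line_id: str
    kind: str
    source: str = "a2"            # "a1" or "a2"
    type: str = ""
    spans: list[tuple[int, int]] = field(default_factory=list)
    text: str = ""
    trigger: str = ""             # event lines: trigger entity id
    args: list[tuple[str, str]] = field(default_factory=list)  # (role, target id)
    members: list[str] = field(default_factory=list)           # equiv lines
    raw: str = ""


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    annotations: list[StandoffLine] = field(default_factory=list)

    def entities(self) -> dict[str, StandoffLine]:
        return {a.line_id: a for a in self.annotations if a.kind == "entity"}

    def given_entities(self) -> dict[str, StandoffLine]:
        return {a.line_id: a for a in self.annotations
                if a.kind == "entity" and a.source == "a1"}

    def equiv_sets(self) -> list[list[str]]:
        return [a.members for a in self.annotations if a.kind == "equiv"]

    def sentence_at(self, offset: int) -> Optional[Sentence]:
        for s in self.sentences:
            if s.char_start <= offset < s.char_end:
                return s
        return None


def _split_sentences(text: str) -> list[Sentence]:
    sentences = []
    pos = 0
    for line in text.split("\n"):
        end = pos + len(line)
        stripped = line.strip()
        if stripped:
            start = pos + (len(line) - len(line.lstrip()))
            sentences.append(Sentence(index=len(sentences),
                                      char_start=start,
                                      char_end=start + len(stripped)))
        pos = end + 1
    return sentences


def _parse_standoff_line(line: str, lineno: int, source: str,
                         text: str, path: str) -> StandoffLine:
    parts = line.split("\t")
    line_id = parts[0]
    try:
        if line_id.startswith("T"):
            if len(parts) < 2:
                raise StandoffParseError(f"{path}:{lineno}: truncated entity line")
            header = parts[1]
            type_, _, offsets = header.partition(" ")
            spans = []
            for frag in offsets.split(";"):
                s, e = frag.split()
                spans.append((int(s), int(e)))
            surface = parts[2] if len(parts) > 2 else ""
            for s, e in spans:
                if not (0 <= s < e <= len(text)):
                    raise OffsetError(
                        f"{path}:{lineno}: span [{s},{e}) outside text of length {len(text)}")
            return StandoffLine(line_id, "entity", source, type=type_,
                                spans=spans, text=surface, raw=line)
        if line_id.startswith("E"):
            fields = parts[1].split()
            type_, _, trigger = fields[0].partition(":")
            args = []
            for f in fields[1:]:
                role, _, target = f.partition(":")
                args.append((role, target))
            return StandoffLine(line_id, "event", source, type=type_,
                                trigger=trigger, args=args, raw=line)
        if line_id.startswith("R"):
            fields = parts[1].split()
            type_ = fields[0]
            args = []
            for f in fields[1:]:
                role, _, target = f.partition(":")
                args.append((role, target))
            return StandoffLine(line_id, "relation", source, type=type_,
                                args=args, raw=line)
        if line_id.startswith("M"):
            type_, target = parts[1].split()
            return StandoffLine(line_id, "modifier", source, type=type_,
                                args=[("Target", target)], raw=line)
        if line_id == "*":
            fields = parts[1].split()
            if len(fields) < 3:
                raise StandoffParseError(
                    f"{path}:{lineno}: equiv line needs >=2 member entities")
            return StandoffLine("*", "equiv", source, type=fields[0],
                                members=fields[1:], raw=line)
    except (StandoffParseError, OffsetError):
        raise
    except Exception as exc:
        raise StandoffParseError(f"{path}:{lineno}: malformed line: {exc}") from exc
    # unknown kinds (e.g. "#" comments) are preserved verbatim
    return StandoffLine(line_id, "other", source, raw=line)


def read_document(txt_path, a1_path, a2_path=None, doc_id: str | None = None) -> Document:
    """Read a standoff-annotated document; ``.a2`` is optional (prediction mode)."""
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    if doc_id is None:
        doc_id = txt_path.stem
    doc = Document(doc_id=doc_id, text=text, sentences=_split_sentences(text))
    for path, source in ((a1_path, "a1"), (a2_path, "a2")):
        if path is None:
            continue
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            ann = _parse_standoff_line(line, lineno, source, text, str(path))
            if ann.kind == "entity" and ann.text:
                got = " ".join(text[s:e] for s, e in ann.spans)
                if got != ann.text and text[ann.spans[0][0]:ann.spans[-1][1]] != ann.text:
                    raise StandoffParseError(
                        f"{path}:{lineno}: entity text {ann.text!r} does not match "
                        f"document substring {got!r}")
            doc.annotations.append(ann)
    return doc


def read_parse(conll_path, doc: Document) -> Document:
    """Attach tokens and dependencies from a CoNLL-style parse file.

    One blank-line-separated block per sentence; columns are
    index/form/stem/POS/head/deprel with head 0 denoting the root. Token
    offsets are recovered by greedy left-to-right alignment against the
    sentence text, so whitespace variations in the text are tolerated.
    A stem column of ``_`` is filled with the Porter stem of the form.
    """
    content = Path(conll_path).read_text(encoding="utf-8")
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in content.splitlines():
        if line.strip():
            current.append(line)
        elif current:
            blocks.append(current)
            current = []
    if current:
        blocks.append(current)
    if len(blocks) != len(doc.sentences):
        raise AlignmentError(
            f"{conll_path}: {len(blocks)} parse blocks for "
            f"{len(doc.sentences)} sentences in {doc.doc_id}")
    for sentence, block in zip(doc.sentences, blocks):
        tokens: list[Token] = []
        deps: list[Dependency] = []
        cursor = sentence.char_start
        rows = []
        for line in block:
            cols = line.split("\t")
            if len(cols) < 6:
                raise StandoffParseError(f"{conll_path}: expected 6 columns, got {cols!r}")
            rows.append(cols)
        for i, cols in enumerate(rows):
            form = cols[1]
            found = doc.text.find(form, cursor, sentence.char_end)
            if found < 0:
                raise AlignmentError(
                    f"{conll_path}: token {form!r} not found in sentence "
                    f"{sentence.index} of {doc.doc_id}")
            if doc.text[cursor:found].strip():
                raise AlignmentError(
                    f"{conll_path}: unparsed text {doc.text[cursor:found]!r} "
                    f"before token {form!r} in {doc.doc_id}")
            tok_stem = cols[2] if cols[2] != "_" else porter_stem(form)
            tokens.append(Token(index=i, text=form, char_start=found,
                                char_end=found + len(form), pos=cols[3],
                                stem=tok_stem))
            cursor = found + len(form)
        for i, cols in enumerate(rows):
            head = int(cols[4])
            if head > 0:
                deps.append(Dependency(governor=head - 1, dependent=i,
                                       dep_type=cols[5]))
        sentence.tokens = tokens
        sentence.dependencies = deps
    return doc


def split_protein_name_tokens(sentence: Sentence,
                              given_entities: Iterable[StandoffLine]) -> Sentence:
    """Split tokens at punctuation adjacent to an embedded entity boundary.

    Handles head-token collisions like "p50/p65" (two entities in one parse
    token) or "GATA3-binding" (entity plus trailing material), where the
    shared head token would otherwise prevent separate events on the parts.
    The fragment containing the original token's first character inherits
    the token's dependencies; every other fragment attaches to it with a
    "punct" (punctuation) or "dep" (other) relation. Idempotent.
    """
    boundaries: set[int] = set()
    for ent in given_entities:
        for s, e in ent.spans:
            boundaries.add(s)
            boundaries.add(e)

    new_tokens: list[Token] = []
    # old token index -> (new index of inheriting fragment, extra fragments)
    inherit: dict[int, int] = {}
    extra_frags: list[tuple[int, Token]] = []  # (inheriting new idx, fragment)

    def cut_positions(tok: Token) -> list[int]:
        cuts = []
        for off in range(tok.char_start, tok.char_end):
            ch = tok.text[off - tok.char_start]
            if ch not in PUNCT_CHARS:
                continue
            # punctuation char at [off, off+1); adjacent entity boundary
            # strictly inside the token on either side of it
            for b in (off, off + 1):
                if b in boundaries and tok.char_start < b < tok.char_end:
                    cuts.append(off)
                    break
        return cuts

    for tok in sentence.tokens:
        cuts = cut_positions(tok)
        if not cuts:
            idx = len(new_tokens)
            new_tokens.append(Token(idx, tok.text, tok.char_start, tok.char_end,
                                    tok.pos, tok.stem))
            inherit[tok.index] = idx
            continue
        # fragment spans between cut punctuation characters
        frags: list[tuple[int, int]] = []
        prev = tok.char_start
        for c in sorted(set(cuts)):
            if c > prev:
                frags.append((prev, c))
            frags.append((c, c + 1))
            prev = c + 1
        if prev < tok.char_end:
            frags.append((prev, tok.char_end))
        inheriting_new_idx = None
        pending: list[Token] = []
        for fs, fe in frags:
            text = tok.text[fs - tok.char_start: fe - tok.char_start]
            is_punct = all(c in PUNCT_CHARS for c in text)
            frag_tok = Token(-1, text, fs, fe,
                             ":" if is_punct else tok.pos,
                             porter_stem(text))
            if fs <= tok.char_start < fe:
                idx = len(new_tokens) + len(pending)
                pending.append(frag_tok)
                inheriting_new_idx = idx
            else:
                pending.append(frag_tok)
        base = len(new_tokens)
        for j, frag_tok in enumerate(pending):
            frag_tok.index = base + j
            new_tokens.append(frag_tok)
        assert inheriting_new_idx is not None
        inherit[tok.index] = inheriting_new_idx
        for frag_tok in new_tokens[base:]:
            if frag_tok.index != inheriting_new_idx:
                extra_frags.append((inheriting_new_idx, frag_tok))

    new_deps = [Dependency(inherit[d.governor], inherit[d.dependent], d.dep_type)
                for d in sentence.dependencies]
    for head_idx, frag_tok in extra_frags:
        rel = "punct" if all(c in PUNCT_CHARS for c in frag_tok.text) else "dep"
        new_deps.append(Dependency(head_idx, frag_tok.index, rel))

    sentence.tokens = new_tokens
    sentence.dependencies = new_deps
    return sentence


def _max_t_id(doc: Document) -> int:
    best = 0
    for a in doc.annotations:
        if a.kind == "entity":
            m = re.match(r"T(\d+)$", a.line_id)
            if m:
                best = max(best, int(m.group(1)))
    return best


def write_a2(events, doc: Document) -> str:
    """Serialize events as ``.a2`` standoff text.

    T lines are emitted for predicted (non-given) trigger/entity nodes with
    ids continuing densely after the ``.a1`` numbering; E lines for triggered
    events, R lines for triggerless relations, M lines for modality flags.
    Equivalence lines read from a ``.a2`` are passed through.
    ``events`` are :class:`eventex.graph.Event` objects whose arguments
    reference :class:`eventex.graph.EntityNode` or nested events.
    """
    lines: list[str] = []
    node_ids: dict[int, str] = {}
    next_t = _max_t_id(doc) + 1

    def node_key(node):
        return id(node)

    def ensure_node(node) -> str:
        nonlocal next_t
        key = node_key(node)
        if key in node_ids:
            return node_ids[key]
        if node.given:
            if not node.node_id:
                raise ValueError(f"given node without id: {node}")
            node_ids[key] = node.node_id
            return node.node_id
        tid = f"T{next_t}"
        next_t += 1
        spans = ";".join(f"{s} {e}" for s, e in node.char_spans)
        surface = " ".join(doc.text[s:e] for s, e in node.char_spans)
        lines.append(f"{tid}\t{node.type} {spans}\t{surface}")
        node_ids[key] = tid
        return tid

    # collect all nodes in document order for dense, deterministic T ids
    def all_nodes(ev, acc):
        if ev.trigger is not None:
            acc.append(ev.trigger)
        for _, target in ev.arguments:
            if hasattr(target, "arguments"):
                all_nodes(target, acc)
            else:
                acc.append(target)

    nodes: list = []
    for ev in events:
        all_nodes(ev, nodes)
    seen = set()
    ordered = []
    for n in nodes:
        if node_key(n) not in seen:
            seen.add(node_key(n))
            ordered.append(n)
    for n in sorted((n for n in ordered if not n.given),
                    key=lambda n: (n.char_spans[0], n.type)):
        ensure_node(n)
    for n in ordered:
        ensure_node(n)

    event_ids: dict[int, str] = {}
    next_e = 1
    next_r = 1
    next_m = 1
    mod_lines: list[str] = []

    def role_label(role: str, position: int) -> str:
        return role if position == 0 else f"{role}{position + 1}"

    def emit_event(ev) -> str:
        nonlocal next_e, next_r, next_m
        key = id(ev)
        if key in event_ids:
            return event_ids[key]
        arg_refs = []
        role_counts: dict[str, int] = {}
        for role, target in ev.arguments:
            if hasattr(target, "arguments"):
                ref = emit_event(target)
            else:
                ref = ensure_node(target)
            n = role_counts.get(role, 0)
            role_counts[role] = n + 1
            arg_refs.append(f"{role_label(role, n)}:{ref}")
        if ev.trigger is not None:
            eid = f"E{next_e}"
            next_e += 1
            trig = ensure_node(ev.trigger)
            lines.append(f"{eid}\t{ev.type}:{trig} " + " ".join(arg_refs)
                         if arg_refs else f"{eid}\t{ev.type}:{trig}")
        else:
            eid = f"R{next_r}"
            next_r += 1
            lines.append(f"{eid}\t{ev.type} " + " ".join(arg_refs))
        event_ids[key] = eid
        if getattr(ev, "negation", False):
            mod_lines.append(f"M{next_m}\tNegation {eid}")
            next_m += 1
        if getattr(ev, "speculation", False):
            mod_lines.append(f"M{next_m}\tSpeculation {eid}")
            next_m += 1
        return eid

    for ev in events:
        emit_event(ev)
    lines.extend(mod_lines)
    for a in doc.annotations:
        if a.kind == "equiv" and a.source == "a2":
            lines.append(a.raw)
    return "\n".join(lines) + ("\n" if lines else "")
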