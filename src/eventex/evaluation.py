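"""Event-level precision/recall/F with approximate-span, recursive matching.

A predicted event matches a gold event when their types are equal, the
predicted trigger overlaps the gold trigger span extended by one token on
each side (approximate span), and their argument lists match role for role
— protein targets by identity (up to declared entity equivalence),
event targets by a recursively matching event. Matching is greedy and
one-to-one, ordered by (type, trigger offset) for determinism.

This evaluator approximates, not replicates, the official per-task scorers
(which are external services and differ per task); all built-in acceptance
checks use it on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from eventex.graph import EntityNode, Event
from eventex.standoff import Document


@dataclass
class MatchCounts:
    per_class: dict[str, list[int]] = field(default_factory=dict)  # type -> [tp, fp, fn]

    def _row(self, cls: str) -> list[int]:
        return self.per_class.setdefault(cls, [0, 0, 0])

    def add_tp(self, cls: str):
        self._row(cls)[0] += 1

    def add_fp(self, cls: str):
        self._row(cls)[1] += 1

    def add_fn(self, cls: str):
        self._row(cls)[2] += 1

    @property
    def tp(self) -> int:
        return sum(r[0] for r in self.per_class.values())

    @property
    def fp(self) -> int:
        return sum(r[1] for r in self.per_class.values())

    @property
    def fn(self) -> int:
        return sum(r[2] for r in self.per_class.values())

    def merge(self, other: "MatchCounts") -> "MatchCounts":
        for cls, (tp, fp, fn) in other.per_class.items():
            row = self._row(cls)
            row[0] += tp
            row[1] += fp
            row[2] += fn
        return self


def prf(counts: MatchCounts | tuple[int, int, int]) -> tuple[float, float, float]:
    """Precision, recall and F-score (harmonic mean); zero denominators
    give zero by convention."""
    if isinstance(counts, MatchCounts):
        tp, fp, fn = counts.tp, counts.fp, counts.fn
    else:
        tp, fp, fn = counts
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def _extended_span(node: EntityNode, doc: Optional[Document],
                   extension_tokens: int) -> tuple[int, int]:
    s = min(a for a, _ in node.char_spans)
    e = max(b for _, b in node.char_spans)
    if doc is None or extension_tokens <= 0:
        return s, e
    sent = doc.sentence_at(s)
    if sent is None or not sent.tokens:
        return s, e
    overlapping = [t.index for t in sent.tokens
                   if t.char_start < e and t.char_end > s]
    if not overlapping:
        return s, e
    lo = max(0, min(overlapping) - extension_tokens)
    hi = min(len(sent.tokens) - 1, max(overlapping) + extension_tokens)
    return sent.tokens[lo].char_start, sent.tokens[hi].char_end


class _Matcher:
    def __init__(self, doc: Optional[Document],
                 equiv_sets: Iterable[list[tuple[int, int]]] = (),
                 extension_tokens: int = 1):
        self.doc = doc
        self.extension_tokens = extension_tokens
        # map exact span tuple -> equivalence class id, for interchangeable
        # entity mentions
        self.equiv_class: dict[tuple, int] = {}
        for k, spans in enumerate(equiv_sets):
            for span in spans:
                self.equiv_class[tuple(span)] = k
        self.memo: dict[tuple[int, int], bool] = {}

    def entity_match(self, gold: EntityNode, pred: EntityNode) -> bool:
        if gold.type != pred.type:
            return False
        gspan = tuple(gold.char_spans[0])
        pspan = tuple(pred.char_spans[0])
        if gspan == pspan and gold.char_spans == pred.char_spans:
            return True
        gc = self.equiv_class.get(gspan)
        return gc is not None and gc == self.equiv_class.get(pspan)

    def trigger_match(self, gold: EntityNode, pred: EntityNode) -> bool:
        gs, ge = _extended_span(gold, self.doc, self.extension_tokens)
        ps = min(a for a, _ in pred.char_spans)
        pe = max(b for _, b in pred.char_spans)
        return ps < ge and pe > gs

    def event_match(self, gold: Event, pred: Event) -> bool:
        key = (id(gold), id(pred))
        if key in self.memo:
            return self.memo[key]
        self.memo[key] = False   # cycle guard; overwritten below
        ok = self._event_match(gold, pred)
        self.memo[key] = ok
        return ok

    def _event_match(self, gold: Event, pred: Event) -> bool:
        if gold.type != pred.type:
            return False
        if (gold.trigger is None) != (pred.trigger is None):
            return False
        if gold.trigger is not None and not self.trigger_match(gold.trigger,
                                                               pred.trigger):
            return False
        if len(gold.arguments) != len(pred.arguments):
            return False
        return self._args_match(list(gold.arguments), list(pred.arguments))

    def _args_match(self, gold_args, pred_args) -> bool:
        if not gold_args:
            return True
        role, gtarget = gold_args[0]
        rest = gold_args[1:]
        for i, (prole, ptarget) in enumerate(pred_args):
            if prole != role:
                continue
            if isinstance(gtarget, Event) != isinstance(ptarget, Event):
                continue
            if isinstance(gtarget, Event):
                if not self.event_match(gtarget, ptarget):
                    continue
            elif not self.entity_match(gtarget, ptarget):
                continue
            if self._args_match(rest, pred_args[:i] + pred_args[i + 1:]):
                return True
        return False


def _sort_key(ev: Event):
    if ev.trigger is not None:
        off = ev.trigger.char_spans[0]
    elif ev.arguments and isinstance(ev.arguments[0][1], EntityNode):
        off = ev.arguments[0][1].char_spans[0]
    else:
        off = (1 << 30, 1 << 30)
    return (ev.type, off)


def match_events(gold: list[Event], predicted: list[Event],
                 doc: Optional[Document] = None,
                 equiv_spans: Iterable[list[tuple[int, int]]] = (),
                 extension_tokens: int = 1,
                 match_modality: bool = False) -> MatchCounts:
    """Greedy one-to-one matching of predicted against gold events within
    one document. Unmatched predictions count as false positives,
    unmatched gold events as false negatives."""
    matcher = _Matcher(doc, equiv_spans, extension_tokens)
    counts = MatchCounts()
    gold_sorted = sorted(gold, key=_sort_key)
    pred_sorted = sorted(predicted, key=_sort_key)
    matched_gold: set[int] = set()
    for pred in pred_sorted:
        hit = None
        for g in gold_sorted:
            if id(g) in matched_gold:
                continue
            if matcher.event_match(g, pred):
                if match_modality and (g.negation != pred.negation
                                       or g.speculation != pred.speculation):
                    continue
                hit = g
                break
        if hit is not None:
            matched_gold.add(id(hit))
            counts.add_tp(pred.type)
        else:
            counts.add_fp(pred.type)
    for g in gold_sorted:
        if id(g) not in matched_gold:
            counts.add_fn(g.type)
    return counts


def report(counts: MatchCounts) -> str:
    """Plain-text per-class and total P/R/F report."""
    lines = [f"{'class':<24}{'TP':>6}{'FP':>6}{'FN':>6}"
             f"{'P':>8}{'R':>8}{'F':>8}"]
    for cls in sorted(counts.per_class):
        tp, fp, fn = counts.per_class[cls]
        p, r, f = prf((tp, fp, fn))
        lines.append(f"{cls:<24}{tp:>6}{fp:>6}{fn:>6}"
                     f"{p:>8.4f}{r:>8.4f}{f:>8.4f}")
    p, r, f = prf(counts)
    lines.append(f"{'TOTAL':<24}{counts.tp:>6}{counts.fp:>6}{counts.fn:>6}"
                 f"{p:>8.4f}{r:>8.4f}{f:>8.4f}")
    return "\n".join(lines)
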