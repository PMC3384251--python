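"""Sparse feature extraction for the classifiers.

Six feature groups: token features (surface, stem, POS, character
N-grams, punctuation/digit flags), sentence features (entity count,
bag of words), dependency chains (walks up to depth three from a token),
dependency-path N-grams between two nodes (used in edge detection),
trigger/entity-node type features, and external lexicon features.

All features are binary except bag-of-words counts. Feature names are
deterministic functions of the input, so identical sentences always
produce identical vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
from scipy.sparse import csr_matrix

from eventex.graph import EntityNode
from eventex.schema import TaskSchema
from eventex.standoff import Sentence, Token

PUNCT = set("/-.,;:()[]{}+'\"?!*&%$#@~`|\\<>=_^")


@dataclass
class SparseExample:
    example_id: str
    features: dict[str, float]
    label: str
    provenance: tuple = ()


class FeatureIndex:
    """Bidirectional feature-name <-> dense integer id map (ids from 1).

    Once frozen the index never grows: unseen feature names at prediction
    time are dropped and counted in :attr:`dropped`.
    """

    def __init__(self):
        self.name_to_id: dict[str, int] = {}
        self.id_to_name: dict[int, str] = {}
        self.frozen = False
        self.dropped = 0

    def __len__(self):
        return len(self.name_to_id)

    def get(self, name: str) -> Optional[int]:
        fid = self.name_to_id.get(name)
        if fid is None:
            if self.frozen:
                self.dropped += 1
                return None
            fid = len(self.name_to_id) + 1
            self.name_to_id[name] = fid
            self.id_to_name[fid] = name
        return fid

    def freeze(self):
        self.frozen = True
        return self

    def transform(self, examples: Iterable[SparseExample]) -> csr_matrix:
        rows, cols, vals = [], [], []
        n = 0
        for i, ex in enumerate(examples):
            n = i + 1
            for name, value in ex.features.items():
                fid = self.get(name)
                if fid is not None:
                    rows.append(i)
                    cols.append(fid - 1)
                    vals.append(value)
        return csr_matrix((vals, (rows, cols)),
                          shape=(n, max(1, len(self.name_to_id))))


# ---------------------------------------------------------------------------
# token and sentence features

def token_features(token: Token, sentence: Sentence | None = None,
                   prefix: str = "") -> dict[str, float]:
    text = token.text
    low = text.lower()
    f = {
        f"{prefix}txt={text}": 1.0,
        f"{prefix}low={low}": 1.0,
        f"{prefix}stem={token.stem}": 1.0,
        f"{prefix}pos={token.pos}": 1.0,
    }
    if any(c in PUNCT for c in text):
        f[f"{prefix}hasPunct"] = 1.0
    if any(c.isdigit() for c in text):
        f[f"{prefix}hasDigit"] = 1.0
    padded = f"^{low}$"
    for n in (2, 3):
        if len(low) >= n:   # no N-grams for tokens shorter than the window
            for i in range(len(padded) - n + 1):
                f[f"{prefix}{n}g={padded[i:i + n]}"] = 1.0
    return f


def sentence_features(sentence: Sentence,
                      entities: Iterable[EntityNode] = ()) -> dict[str, float]:
    f: dict[str, float] = {f"numEntities={sum(1 for _ in entities)}": 1.0}
    for t in sentence.tokens:
        name = f"bow={t.text.lower()}"
        f[name] = f.get(name, 0.0) + 1.0
    return f


# ---------------------------------------------------------------------------
# dependency structure helpers

def _adjacency(sentence: Sentence) -> dict[int, list[tuple[int, str, str]]]:
    """token index -> [(neighbour, dep type, step direction)]; direction is
    'gov' when moving from dependent to its governor, 'dep' otherwise."""
    adj: dict[int, list[tuple[int, str, str]]] = {t.index: [] for t in sentence.tokens}
    for d in sentence.dependencies:
        if d.governor == d.dependent:
            continue
        adj[d.dependent].append((d.governor, d.dep_type, "gov"))
        adj[d.governor].append((d.dependent, d.dep_type, "dep"))
    for steps in adj.values():
        steps.sort()
    return adj


def dependency_chain_features(token: Token, sentence: Sentence,
                              depth: int = 3,
                              prefix: str = "") -> dict[str, float]:
    """Walks of length 1..depth along dependencies (undirected, no token
    revisited), encoded as the dependency-type sequence with per-step
    directions, alone and with end-token attributes."""
    adj = _adjacency(sentence)
    tokens = {t.index: t for t in sentence.tokens}
    f: dict[str, float] = {}

    def walk(idx: int, path: list[str], visited: set[int]):
        if len(path) >= depth:
            return
        for nxt, dep_type, direction in adj.get(idx, ()):
            if nxt in visited:
                continue
            step = f"{dep_type}.{direction}"
            new_path = path + [step]
            base = f"{prefix}chain{len(new_path)}:" + ":".join(new_path)
            end = tokens[nxt]
            f[base] = 1.0
            f[f"{base}>txt={end.text}"] = 1.0
            f[f"{base}>pos={end.pos}"] = 1.0
            f[f"{base}>stem={end.stem}"] = 1.0
            walk(nxt, new_path, visited | {nxt})

    walk(token.index, [], {token.index})
    return f


def _token_graph(sentence: Sentence) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(t.index for t in sentence.tokens)
    for d in sentence.dependencies:
        if d.governor == d.dependent:
            continue
        if g.has_edge(d.governor, d.dependent):
            # keep the lexicographically smallest label for determinism
            if d.dep_type < g.edges[d.governor, d.dependent]["dep"].dep_type:
                g.edges[d.governor, d.dependent]["dep"] = d
        else:
            g.add_edge(d.governor, d.dependent, dep=d)
    return g


def shortest_token_path(sentence: Sentence, a: int, b: int) -> Optional[list[int]]:
    """One shortest undirected path between two token indices; among equal
    length paths the lexicographically smallest token-index sequence wins."""
    g = _token_graph(sentence)
    if a not in g or b not in g:
        return None
    try:
        paths = list(nx.all_shortest_paths(g, a, b))
    except nx.NetworkXNoPath:
        return None
    return min(paths)


def path_ngram_features(node_a: EntityNode, node_b: EntityNode,
                        sentence: Sentence, prefix: str = "") -> dict[str, float]:
    """Dependency-path N-grams between the head tokens of two nodes.

    Internal tokens yield (left dep, token attribute, right dep) trigrams;
    each dependency yields (left token attribute, dep, right token attribute)
    trigrams; both are emitted for the path and its mirror so they are
    symmetric under argument swap. Governor-dependent directions of
    individual dependencies yield direction-tagged token bigrams, which
    invert under swap. Disconnected pairs yield only a "noPath" feature.
    """
    f: dict[str, float] = {}
    path = shortest_token_path(sentence, node_a.head_token, node_b.head_token)
    if path is None or len(path) < 2:
        if path is None:
            f[f"{prefix}noPath"] = 1.0
        else:
            f[f"{prefix}sameHead"] = 1.0
        return f
    tokens = {t.index: t for t in sentence.tokens}
    g = _token_graph(sentence)
    deps = [g.edges[path[i], path[i + 1]]["dep"] for i in range(len(path) - 1)]
    f[f"{prefix}pathLen={len(path) - 1}"] = 1.0

    def attrs(idx: int) -> list[tuple[str, str]]:
        t = tokens[idx]
        return [("txt", t.text), ("pos", t.pos), ("stem", t.stem)]

    # dependency-centred trigrams
    for i, d in enumerate(deps):
        left, right = path[i], path[i + 1]
        for (ka, va), (kb, vb) in zip(attrs(left), attrs(right)):
            f[f"{prefix}dTri:{va}:{d.dep_type}:{vb}"] = 1.0
            f[f"{prefix}dTri:{vb}:{d.dep_type}:{va}"] = 1.0
    # internal-token-centred trigrams
    for i in range(1, len(path) - 1):
        dl, dr = deps[i - 1].dep_type, deps[i].dep_type
        for k, v in attrs(path[i]):
            f[f"{prefix}tTri:{dl}:{v}:{dr}"] = 1.0
            f[f"{prefix}tTri:{dr}:{v}:{dl}"] = 1.0
    # direction-tagged token bigrams along the a->b orientation
    for i, d in enumerate(deps):
        left, right = path[i], path[i + 1]
        arrow = ">" if d.governor == left else "<"
        f[f"{prefix}dir:{tokens[left].text}:{arrow}{d.dep_type}:{tokens[right].text}"] = 1.0
    return f


# ---------------------------------------------------------------------------
# node-type and external features

def trigger_node_features(node: EntityNode, schema: TaskSchema,
                          prefix: str = "") -> dict[str, float]:
    if not node.type:
        return {}
    f = {f"{prefix}type={node.type}": 1.0}
    sup = schema.supertype(node.type)
    if sup:
        f[f"{prefix}supertype={sup}"] = 1.0
        f[f"{prefix}typePair={node.type}&{sup}"] = 1.0
    if node.given:
        f[f"{prefix}given"] = 1.0
    return f


def node_pair_features(node_a: EntityNode, node_b: EntityNode,
                       schema: TaskSchema) -> dict[str, float]:
    f = {f"pair={node_a.type}-{node_b.type}": 1.0}
    f.update(trigger_node_features(node_a, schema, prefix="src_"))
    f.update(trigger_node_features(node_b, schema, prefix="dst_"))
    sa, sb = schema.supertype(node_a.type), schema.supertype(node_b.type)
    if sa or sb:
        f[f"superPair={sa or node_a.type}-{sb or node_b.type}"] = 1.0
    return f


@dataclass
class Lexicons:
    """External lexical resources, loaded from plain-text files."""
    bacterium_substrings: set[str] = field(default_factory=set)
    synonym_pairs: set[frozenset] = field(default_factory=set)
    speculation_words: set[str] = field(default_factory=set)
    multitoken_triggers: set[str] = field(default_factory=set)
    hypernyms: dict[str, set[str]] = field(default_factory=dict)

    @staticmethod
    def _read_lines(path) -> list[str]:
        from pathlib import Path
        p = Path(path)
        if not p.is_file():
            raise FileNotFoundError(f"lexicon file not found: {path}")
        return [ln.strip() for ln in p.read_text(encoding="utf-8").splitlines()
                if ln.strip() and not ln.startswith("#")]

    @classmethod
    def load(cls, bacterium=None, synonyms=None, speculation=None,
             multitoken=None) -> "Lexicons":
        lex = cls()
        if bacterium:
            lex.bacterium_substrings = {w.lower() for w in cls._read_lines(bacterium)}
        if synonyms:
            for line in cls._read_lines(synonyms):
                parts = line.split("\t")
                if len(parts) >= 2:
                    lex.synonym_pairs.add(frozenset(p.lower() for p in parts[:2]))
        if speculation:
            lex.speculation_words = {w.lower() for w in cls._read_lines(speculation)}
        if multitoken:
            lex.multitoken_triggers = {w.lower() for w in cls._read_lines(multitoken)}
        return lex


def token_external_features(token: Token, sentence: Sentence,
                            lexicons: Lexicons | None,
                            prefix: str = "") -> dict[str, float]:
    if lexicons is None:
        return {}
    f: dict[str, float] = {}
    low = token.text.lower()
    if low in lexicons.bacterium_substrings:
        f[f"{prefix}bacteriumName"] = 1.0
    if low in lexicons.speculation_words:
        f[f"{prefix}specWord"] = 1.0
    for h in lexicons.hypernyms.get(low, ()):
        f[f"{prefix}hyper={h}"] = 1.0
    if lexicons.multitoken_triggers:
        # join the texts of up to three preceding tokens with this one and
        # flag the presence of a known multi-token trigger string
        idx = token.index
        toks = sentence.tokens
        for back in range(1, 4):
            if idx - back < 0:
                break
            joined = " ".join(t.text.lower() for t in toks[idx - back: idx + 1])
            if joined in lexicons.multitoken_triggers:
                f[f"{prefix}knownMultiTok"] = 1.0
                f[f"{prefix}knownMultiTokLen={back + 1}"] = 1.0
    return f


def pair_external_features(node_a: EntityNode, node_b: EntityNode,
                           lexicons: Lexicons | None) -> dict[str, float]:
    if lexicons is None:
        return {}
    f: dict[str, float] = {}
    if lexicons.synonym_pairs:
        key = frozenset((node_a.text.lower(), node_b.text.lower()))
        if key in lexicons.synonym_pairs:
            f["synonymPair"] = 1.0
    return f
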