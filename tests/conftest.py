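import random

import pytest

from eventex.graph import EntityNode, Event
from eventex.schema import load_schema
from eventex.standoff import Dependency, Sentence, Token
from eventex.stemming import stem as porter_stem
from eventex.synthetic import CorpusSpec, generate


@pytest.fixture(scope="session")
def ge_schema():
    return load_schema("ge")


@pytest.fixture(scope="session")
def epi_schema():
    return load_schema("epi")


@pytest.fixture(scope="session")
def ren_schema():
    return load_schema("ren")


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A small on-disk synthetic corpus shared across the suite."""
    root = tmp_path_factory.mktemp("corpus")
    spec = CorpusSpec(n_train=30, n_devel=10, n_test=5, seed=11)
    return generate(spec, root)


def make_sentence(text: str, deps=(), pos=None, index=0, offset=0) -> Sentence:
    """Build a single-space-tokenized sentence with explicit dependencies.

    ``deps`` are (governor, dependent, type) token-index triples; POS tags
    default to a crude guess and stems to Porter stems.
    """
    words = text.split()
    tokens = []
    cursor = offset
    for i, w in enumerate(words):
        tokens.append(Token(index=i, text=w, char_start=cursor,
                            char_end=cursor + len(w),
                            pos=(pos[i] if pos else "NN"),
                            stem=porter_stem(w)))
        cursor += len(w) + 1
    sent = Sentence(index=index, char_start=offset,
                    char_end=offset + len(text))
    sent.tokens = tokens
    sent.dependencies = [Dependency(g, d, t) for g, d, t in deps]
    return sent


def make_entity(node_id, etype, sentence, token_index, given=True,
                sentence_index=None) -> EntityNode:
    tok = sentence.tokens[token_index]
    return EntityNode(node_id=node_id, type=etype, head_token=token_index,
                      char_spans=[(tok.char_start, tok.char_end)],
                      given=given, text=tok.text,
                      sentence_index=sentence.index
                      if sentence_index is None else sentence_index)


def make_event(event_id, etype, trigger, *args, negation=False,
               speculation=False) -> Event:
    return Event(event_id=event_id, type=etype, trigger=trigger,
                 arguments=list(args), negation=negation,
                 speculation=speculation)


@pytest.fixture
def rng():
    return random.Random(20240901)
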