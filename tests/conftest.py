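import pathlib

import pytest

from openvocab.corpus import AuthorCorpus, Message
from openvocab.tokenizer import tokenize

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> pathlib.Path:
    return DATA


@pytest.fixture()
def tiny_corpus() -> AuthorCorpus:
    """Three authors with hand-countable messages."""
    msgs = [
        Message("a", "i love you", "m1"),
        Message("a", "love the day", "m2"),
        Message("b", "happy day :-)", "m1"),
        Message("b", "", "m2"),
        Message("c", "the the the day", "m1"),
    ]
    corpus = AuthorCorpus()
    for m in msgs:
        corpus.add(m, tokenize(m.text))
    return corpus
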