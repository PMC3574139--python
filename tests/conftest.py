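import pytest

from medtopic.corpus_io import Corpus, Message
from medtopic.lexicon import Lexicon
from medtopic.preprocess import PreprocessConfig


def make_message(i, text, author="a1", **kw):
    return Message(id=f"m{i}", author_id=author, text=text, **kw)


def make_corpus(texts, authors=None, **kw):
    authors = authors or ["a1"] * len(texts)
    return Corpus(messages=[make_message(i, t, a)
                            for i, (t, a) in enumerate(zip(texts, authors))], **kw)


@pytest.fixture
def tiny_lexicon():
    """A small hand-built lexicon with single- and multi-token terms."""
    return Lexicon.from_term_strings({
        "chest pain": {"sosy"},
        "pain": {"sosy"},
        "shortness of breath": {"sosy"},
        "breath": {"bpoc"},
        "chemo": {"topp"},
        "tamoxifen": {"phsu", "orch"},
        "infection": {"dsyn", "patf"},
        "biopsy": {"diap"},
    })


@pytest.fixture
def plain_config():
    """Preprocessing without a stoplist, no minimum message length."""
    return PreprocessConfig(stoplist=frozenset(), min_token_len=1,
                           noise_min_content_tokens=0)
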