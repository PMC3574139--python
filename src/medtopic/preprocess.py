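"""Tokenization, normalization and noise filtering of forum messages.

Messages are lowercased and split into word tokens (intra-word hyphens and
apostrophes kept, so "x-ray" and "paget's" survive as single tokens).
Content tokens are the raw tokens minus stop words and too-short tokens,
Porter-stemmed. "Emotional" messages that carry no medical content — e.g.
"Thank you for your answer" — are removed by requiring a minimum number of
content tokens and at least one medical-lexicon match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from ._porter import porter_stem
from .corpus_io import Corpus, Message

__all__ = [
    "PreprocessConfig",
    "TokenizedMessage",
    "default_stoplist",
    "load_stoplist",
    "stem_token",
    "tokenize_and_normalize",
    "tokenize_corpus",
    "filter_noise_messages",
]

_TOKEN_RE = re.compile(r"[0-9a-zÀ-ɏ]+(?:['’-][0-9a-zÀ-ɏ]+)*")
_ALPHA_RE = re.compile(r"[a-z]+\Z")


def load_stoplist(path) -> frozenset[str]:
    """One lowercase word per line; '#' starts a comment."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        word = line.split("#", 1)[0].strip().lower()
        if word:
            words.add(word)
    return frozenset(words)


def default_stoplist() -> frozenset[str]:
    """The packaged default English stop-word list."""
    ref = resources.files("medtopic.data").joinpath("stopwords.txt")
    with resources.as_file(ref) as path:
        return load_stoplist(path)


@dataclass(frozen=True)
class PreprocessConfig:
    stoplist: frozenset[str] = field(default_factory=default_stoplist)
    use_stemming: bool = True
    min_token_len: int = 2
    noise_min_content_tokens: int = 3

    def __post_init__(self):
        if self.min_token_len < 1:
            raise ValueError("min_token_len must be >= 1")
        if self.noise_min_content_tokens < 0:
            raise ValueError("noise_min_content_tokens must be >= 0")
        if any(w != w.lower() for w in self.stoplist):
            raise ValueError("stoplist entries must be lowercase")


@dataclass(frozen=True)
class TokenizedMessage:
    message_id: str
    raw_tokens: tuple[str, ...]
    content_tokens: tuple[str, ...]


def stem_token(token: str) -> str:
    """Porter-stem purely alphabetic tokens; leave others (hyphenated,
    apostrophes, digits) as-is so "x-ray" matches itself."""
    return porter_stem(token) if _ALPHA_RE.match(token) else token


def tokenize_and_normalize(message: Message, config: PreprocessConfig) -> TokenizedMessage:
    """Pure per-message tokenization: lowercase word tokens, then stop-word /
    length filtering and (optionally) stemming to produce content tokens."""
    raw = tuple(_TOKEN_RE.findall(message.text.lower()))
    content = []
    for tok in raw:
        if tok in config.stoplist or len(tok) < config.min_token_len:
            continue
        content.append(stem_token(tok) if config.use_stemming else tok)
    return TokenizedMessage(message_id=message.id, raw_tokens=raw,
                            content_tokens=tuple(content))


def tokenize_corpus(corpus: Corpus, config: PreprocessConfig) -> list[TokenizedMessage]:
    return [tokenize_and_normalize(m, config) for m in corpus]


def filter_noise_messages(corpus: Corpus, tokenized: list[TokenizedMessage],
                          lexicon, config: PreprocessConfig) -> Corpus:
    """Drop medically-empty messages.

    A message is retained iff it has at least ``noise_min_content_tokens``
    content tokens AND at least one lexicon term match. ``tokenized`` must
    align one-to-one with ``corpus`` by message id; relative order is
    preserved. Filtering is idempotent.
    """
    from .lexicon import match_terms

    if len(tokenized) != len(corpus):
        raise ValueError("tokenized list does not align with corpus (length mismatch)")
    kept = []
    for msg, tok in zip(corpus, tokenized):
        if msg.id != tok.message_id:
            raise ValueError(
                f"tokenized list misaligned with corpus at message {msg.id!r}"
            )
        if len(tok.content_tokens) < config.noise_min_content_tokens:
            continue
        if not match_terms(list(tok.content_tokens), lexicon):
            continue
        kept.append(msg)
    return Corpus(messages=kept, board_name=corpus.board_name,
                  disease_type=corpus.disease_type)
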