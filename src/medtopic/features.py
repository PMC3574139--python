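"""Five-block bag-of-words feature matrices for message clustering.

Each message is represented by raw occurrence counts over five disjoint
column blocks:

    unigram | bigram | trigram | med_term | sem_type

The three n-gram blocks are the keyword-based features (F1), built from the
contiguous content-token sequence and thresholded at ``min_df`` distinct
messages. The medical-term and semantic-type blocks are the domain-specific
features (F2): per-message lexicon match counts, and match counts aggregated
over the 20 semantic types (a term carrying two types increments both type
columns). Counts are raw — downstream PCA centering absorbs scale — with an
optional per-message length normalization switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .lexicon import Lexicon, TermMatch, default_semantic_types, match_terms
from .preprocess import TokenizedMessage

__all__ = [
    "BLOCKS",
    "F1_BLOCKS",
    "F2_BLOCKS",
    "Vocabulary",
    "FeatureMatrix",
    "match_corpus",
    "build_vocabulary",
    "vectorize",
    "select_blocks",
]

BLOCKS = ("unigram", "bigram", "trigram", "med_term", "sem_type")
F1_BLOCKS = frozenset({"unigram", "bigram", "trigram"})
F2_BLOCKS = frozenset({"med_term", "sem_type"})


def match_corpus(tokenized: Sequence[TokenizedMessage],
                 lexicon: Lexicon) -> dict[str, list[TermMatch]]:
    """Run the lexicon matcher over every message's content tokens."""
    out: dict[str, list[TermMatch]] = {}
    for tok in tokenized:
        ms = match_terms(list(tok.content_tokens), lexicon)
        out[tok.message_id] = [
            TermMatch(message_id=tok.message_id, term=m.term,
                      start_token_index=m.start_token_index,
                      end_token_index=m.end_token_index, types=m.types)
            for m in ms
        ]
    return out


def _ngrams(tokens: Sequence[str], n: int) -> Iterable[str]:
    for i in range(len(tokens) - n + 1):
        yield " ".join(tokens[i:i + n])


@dataclass
class Vocabulary:
    unigrams: list[str]
    bigrams: list[str]
    trigrams: list[str]
    med_terms: list[str]
    sem_types: list[str]
    min_df: int
    column_index: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.column_index:
            col = 0
            for block, terms in zip(BLOCKS, self._block_lists()):
                for t in terms:
                    self.column_index[(block, t)] = col
                    col += 1

    def _block_lists(self):
        return (self.unigrams, self.bigrams, self.trigrams,
                self.med_terms, self.sem_types)

    @property
    def n_features(self) -> int:
        return sum(len(b) for b in self._block_lists())

    def block_slice(self, block: str) -> slice:
        sizes = [len(b) for b in self._block_lists()]
        start = sum(sizes[:BLOCKS.index(block)])
        return slice(start, start + sizes[BLOCKS.index(block)])

    def column_labels(self) -> list[tuple[str, str]]:
        labels: list[tuple[str, str]] = [None] * self.n_features  # type: ignore
        for key, col in self.column_index.items():
            labels[col] = key
        return labels


@dataclass
class FeatureMatrix:
    row_ids: list[str]
    values: np.ndarray  # n_messages x n_features, non-negative
    vocabulary: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_vocabulary(tokenized: Sequence[TokenizedMessage],
                     matches: Mapping[str, Sequence[TermMatch]],
                     min_df: int = 3,
                     semantic_types: Optional[Sequence[str]] = None) -> Vocabulary:
    """Collect the five feature blocks.

    n-grams (n=1,2,3) over contiguous content tokens must occur in at least
    ``min_df`` distinct messages; medical terms are every matched term; the
    semantic-type block is always the full packaged type list.
    """
    if min_df < 1:
        raise ValueError("min_df must be >= 1")
    if not tokenized:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    df: list[dict[str, int]] = [{}, {}, {}]
    for tok in tokenized:
        for n in (1, 2, 3):
            for g in set(_ngrams(tok.content_tokens, n)):
                df[n - 1][g] = df[n - 1].get(g, 0) + 1
    grams = [sorted(g for g, c in df[n].items() if c >= min_df) for n in range(3)]
    med_terms = sorted({m.term for ms in matches.values() for m in ms})
    if semantic_types is None:
        semantic_types = sorted(default_semantic_types())
    return Vocabulary(unigrams=grams[0], bigrams=grams[1], trigrams=grams[2],
                      med_terms=med_terms, sem_types=list(semantic_types),
                      min_df=min_df)


def vectorize(tokenized: Sequence[TokenizedMessage],
              matches: Mapping[str, Sequence[TermMatch]],
              vocabulary: Vocabulary,
              length_normalize: bool = False) -> FeatureMatrix:
    """Count features per message against a fixed vocabulary.

    n-gram cells are raw occurrence counts; med_term cells are match counts;
    a sem_type cell is the total count of matches whose type set contains
    that type (a two-type term increments two columns).
    """
    unknown = set(matches) - {t.message_id for t in tokenized}
    if unknown:
        raise ValueError(f"matches reference unknown message id(s): {sorted(unknown)[:3]}")
    idx = vocabulary.column_index
    X = np.zeros((len(tokenized), vocabulary.n_features), dtype=np.float64)
    for row, tok in enumerate(tokenized):
        for n, block in ((1, "unigram"), (2, "bigram"), (3, "trigram")):
            for g in _ngrams(tok.content_tokens, n):
                col = idx.get((block, g))
                if col is not None:
                    X[row, col] += 1
        for m in matches.get(tok.message_id, ()):
            col = idx.get(("med_term", m.term))
            if col is not None:
                X[row, col] += 1
            for t in m.types:
                col = idx.get(("sem_type", t))
                if col is not None:
                    X[row, col] += 1
        if length_normalize and tok.content_tokens:
            X[row] /= len(tok.content_tokens)
    return FeatureMatrix(row_ids=[t.message_id for t in tokenized],
                         values=X, vocabulary=vocabulary)


def select_blocks(matrix: FeatureMatrix, blocks: Iterable[str]) -> FeatureMatrix:
    """Column-slice a feature matrix down to the given blocks.

    ``F1`` = {unigram, bigram, trigram}; ``F2`` = {med_term, sem_type}.
    """
    blocks = set(blocks)
    if not blocks:
        raise ValueError("block set must be non-empty")
    unknown = blocks - set(BLOCKS)
    if unknown:
        raise ValueError(f"unknown block(s): {sorted(unknown)}")
    voc = matrix.vocabulary
    keep_cols: list[int] = []
    kept = {b: [] for b in BLOCKS}
    for block in BLOCKS:
        if block not in blocks:
            continue
        sl = voc.block_slice(block)
        keep_cols.extend(range(sl.start, sl.stop))
        kept[block] = list(voc._block_lists()[BLOCKS.index(block)])
    new_voc = Vocabulary(unigrams=kept["unigram"], bigrams=kept["bigram"],
                         trigrams=kept["trigram"], med_terms=kept["med_term"],
                         sem_types=kept["sem_type"], min_df=voc.min_df)
    return FeatureMatrix(row_ids=list(matrix.row_ids),
                         values=matrix.values[:, keep_cols].copy(),
                         vocabulary=new_voc)
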