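"""Dictionary-based medical term matching with semantic-type assignment.

A lightweight stand-in for concept mapping against a biomedical
metathesaurus: a term lexicon maps multiword medical terms (1-5 stemmed
tokens) to one or more of 20 coarse semantic types (e.g. ``sosy`` = Sign or
Symptom, ``phsu`` = Pharmacologic Substance). Matching is greedy
left-to-right longest-match over stemmed tokens, emitting non-overlapping
spans — a deliberate simplification of full concept mapping (no variant
generation, no word-sense disambiguation), adequate because downstream
features only use term frequencies per semantic type.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .preprocess import stem_token

__all__ = [
    "SemanticType",
    "TermMatch",
    "Lexicon",
    "load_semantic_types",
    "default_semantic_types",
    "load_lexicon",
    "default_lexicon",
    "match_terms",
]


@dataclass(frozen=True)
class SemanticType:
    abbrev: str
    name: str


@dataclass(frozen=True)
class TermMatch:
    message_id: Optional[str]
    term: str
    start_token_index: int
    end_token_index: int  # exclusive
    types: frozenset[str]


def load_semantic_types(path) -> dict[str, SemanticType]:
    types: dict[str, SemanticType] = {}
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        abbrev, name = line.split("\t")
        if abbrev in types:
            raise ValueError(f"line {line_no}: duplicate semantic type {abbrev!r}")
        types[abbrev] = SemanticType(abbrev=abbrev, name=name)
    return types


def default_semantic_types() -> dict[str, SemanticType]:
    """The packaged closed set of 20 semantic types."""
    ref = resources.files("medtopic.data").joinpath("semantic_types.tsv")
    with resources.as_file(ref) as path:
        return load_semantic_types(path)


class Lexicon:
    """Exact lookup from stemmed token sequences to semantic-type sets."""

    def __init__(self, entries: Mapping[tuple[str, ...], frozenset[str]],
                 semantic_types: Optional[dict[str, SemanticType]] = None):
        self.semantic_types = semantic_types or default_semantic_types()
        for term, types in entries.items():
            if not term or any(not t for t in term):
                raise ValueError(f"empty term {term!r}")
            unknown = set(types) - set(self.semantic_types)
            if unknown:
                raise ValueError(f"unknown semantic type(s) {sorted(unknown)} for term {term!r}")
            if not types:
                raise ValueError(f"term {term!r} has no semantic types")
        self.entries: dict[tuple[str, ...], frozenset[str]] = dict(entries)
        self.max_term_len = max((len(t) for t in entries), default=0)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: tuple[str, ...]) -> bool:
        return term in self.entries

    @classmethod
    def from_term_strings(cls, terms: Mapping[str, set[str]],
                          semantic_types=None, stem: bool = True,
                          stoplist: Optional[frozenset[str]] = None) -> "Lexicon":
        """Build from whitespace-separated term strings, normalizing tokens
        the same way messages are normalized. Duplicate terms (after
        normalization) are merged by type-set union."""
        entries: dict[tuple[str, ...], set[str]] = {}
        for term, types in terms.items():
            toks = [t for t in term.lower().split()
                    if stoplist is None or t not in stoplist]
            if stem:
                toks = [stem_token(t) for t in toks]
            if not toks:
                raise ValueError(f"term {term!r} normalizes to nothing")
            if len(toks) > 5:
                raise ValueError(f"term {term!r} exceeds 5 tokens")
            entries.setdefault(tuple(toks), set()).update(types)
        return cls({k: frozenset(v) for k, v in entries.items()}, semantic_types)


def load_lexicon(path, semantic_types=None, stem: bool = True,
                 stoplist: Optional[frozenset[str]] = None) -> Lexicon:
    """Load a TSV lexicon: ``term<TAB>type1|type2``.

    Terms are lowercased and stemmed with the same stemmer as message
    preprocessing; duplicate term lines merge their type sets. An unknown
    type abbreviation or empty term is an error naming the line.
    """
    semantic_types = semantic_types or default_semantic_types()
    terms: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {line_no}: expected term<TAB>types")
        term, type_field = parts
        if not term.strip():
            raise ValueError(f"line {line_no}: empty term")
        types = {t.strip() for t in type_field.split("|") if t.strip()}
        if not types:
            raise ValueError(f"line {line_no}: no semantic types for {term!r}")
        for t in types:
            if t not in semantic_types:
                raise ValueError(f"line {line_no}: unknown semantic type {t!r}")
        terms.setdefault(term, set()).update(types)
    return Lexicon.from_term_strings(terms, semantic_types, stem=stem, stoplist=stoplist)


def default_lexicon() -> Lexicon:
    """The packaged toy lexicon (a small typed vocabulary of common
    oncology/diabetes forum terms; a miniature stand-in for a licensed
    metathesaurus, which cannot be redistributed)."""
    ref = resources.files("medtopic.data").joinpath("toy_lexicon.tsv")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def match_terms(tokens: Sequence[str], lexicon: Lexicon) -> list[TermMatch]:
    """Greedy left-to-right longest-match scan over stemmed tokens.

    At each position the longest lexicon entry starting there is taken; the
    scan then advances past it, so matches never overlap and appear in
    position order.
    """
    matches: list[TermMatch] = []
    n = len(tokens)
    i = 0
    while i < n:
        hit = None
        for length in range(min(lexicon.max_term_len, n - i), 0, -1):
            span = tuple(tokens[i:i + length])
            types = lexicon.entries.get(span)
            if types is not None:
                hit = (length, span, types)
                break
        if hit is None:
            i += 1
            continue
        length, span, types = hit
        matches.append(TermMatch(message_id=None, term=" ".join(span),
                                 start_token_index=i, end_token_index=i + length,
                                 types=types))
        i += length
    return matches
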