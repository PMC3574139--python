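"""Labeled synthetic corpora with the statistical structure the pipeline
assumes: a testbed replacing an unavailable forum scrape.

Each corpus has K latent topics. A non-noise message draws its topic
uniformly, then emits topic-characteristic medical terms (each typed with
its topic's designated semantic type) mixed with background vocabulary; a
``separation`` parameter controls what fraction of a message's term mass
comes from its own topic's term set. A configurable fraction of messages
is medically-empty "emotional" noise ("thank you for your answer", ...)
carrying no lexicon term, to exercise the noise-filtering stage.

Emission is bag-of-words Poisson — the pipeline only consumes token
counts, so richer text generation would add nothing testable. Background
token probabilities follow a Zipf profile, mimicking natural word-frequency
skew. Generation is fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus_io import Corpus, Message
from .lexicon import Lexicon, default_semantic_types

__all__ = ["SyntheticConfig", "SyntheticCorpus", "generate_corpus",
           "write_lexicon_tsv", "NOISE_MARKER"]

NOISE_MARKER = -1

_TYPE_CYCLE = ("sosy", "dsyn", "diap", "topp", "phsu")

_NOISE_PHRASES = (
    "thank you for your answer",
    "i hope you get well soon",
    "sending hugs your way",
    "thinking of you today",
    "best wishes to you all",
    "so sorry to hear that",
    "stay strong you can do it",
    "take care and good luck",
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_topics: int = 5
    n_messages: int = 2000
    background_vocab_size: int = 300
    terms_per_topic: int = 20
    topic_term_rate: float = 6.0     # expected topic-term tokens per message
    background_rate: float = 12.0    # expected background tokens per message
    noise_rate: float = 0.1          # fraction of medically-empty messages
    separation: float = 0.9          # own-topic share of a message's term draws
    multiword_fraction: float = 0.3  # share of two-token terms per topic
    type_profile: Optional[tuple[str, ...]] = None  # per-topic semantic type
    seed: int = 0

    def __post_init__(self):
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.n_messages < 1:
            raise ValueError("n_messages must be >= 1")
        if self.background_vocab_size < 1:
            raise ValueError("background_vocab_size must be >= 1")
        if self.terms_per_topic < 1:
            raise ValueError("terms_per_topic must be >= 1")
        if self.topic_term_rate <= 0:
            raise ValueError("topic_term_rate must be > 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if not (1.0 / self.n_topics) < self.separation <= 1.0 and self.n_topics > 1:
            raise ValueError("separation must be in (1/K, 1]")
        if self.type_profile is not None and len(self.type_profile) != self.n_topics:
            raise ValueError("type_profile length must equal n_topics")

    def resolved_type_profile(self) -> tuple[str, ...]:
        if self.type_profile is not None:
            return self.type_profile
        return tuple(_TYPE_CYCLE[t % len(_TYPE_CYCLE)] for t in range(self.n_topics))


@dataclass
class SyntheticCorpus:
    corpus: Corpus
    lexicon: Lexicon
    truth: list[int]                      # per-message topic index, -1 = noise
    topic_terms: list[list[str]] = field(default_factory=list)
    type_profile: tuple[str, ...] = ()


def _topic_term_sets(config: SyntheticConfig,
                     rng: np.random.Generator) -> list[list[tuple[str, ...]]]:
    """Disjoint per-topic term vocabularies (tokens carry the topic tag, so
    ground-truth recovery is well-posed)."""
    sets = []
    for t in range(config.n_topics):
        terms = []
        for j in range(config.terms_per_topic):
            if rng.random() < config.multiword_fraction:
                terms.append((f"t{t}med{j}", f"t{t}med{j}x"))
            else:
                terms.append((f"t{t}med{j}",))
        sets.append(terms)
    return sets


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate a labeled corpus plus its matching lexicon.

    Non-noise messages always contain at least one topic term (the Poisson
    draw for topic-term count is clamped to >= 1); noise messages contain
    none. Gold labels are the topic's category name when the type profile
    is unambiguous, else ``topic<k>``.
    """
    rng = np.random.default_rng(config.seed)
    profile = config.resolved_type_profile()
    term_sets = _topic_term_sets(config, rng)

    background = [f"bg{i}" for i in range(config.background_vocab_size)]
    zipf = 1.0 / np.arange(1, config.background_vocab_size + 1)
    zipf /= zipf.sum()

    from .keyphrase import TYPE_TO_CATEGORY
    categories = [TYPE_TO_CATEGORY.get(t, "Other") for t in profile]
    unambiguous = len(set(categories)) == len(categories)
    gold_names = categories if unambiguous else [f"topic{k}" for k in range(config.n_topics)]

    n_authors = max(1, config.n_messages // 3)
    start = date(2004, 3, 1)
    messages: list[Message] = []
    truth: list[int] = []
    for i in range(config.n_messages):
        author = f"u{rng.integers(n_authors):05d}"
        ts = (start + timedelta(days=int(rng.integers(0, 8 * 365)))).isoformat()
        is_noise = rng.random() < config.noise_rate
        n_bg = int(rng.poisson(config.background_rate))
        units: list[tuple[str, ...]] = []
        if is_noise:
            phrase = _NOISE_PHRASES[rng.integers(len(_NOISE_PHRASES))]
            units.append(tuple(phrase.split()))
            topic = NOISE_MARKER
            gold = None
        else:
            topic = int(rng.integers(config.n_topics))
            gold = gold_names[topic]
            n_terms = max(1, int(rng.poisson(config.topic_term_rate)))
            for _ in range(n_terms):
                if config.n_topics > 1 and rng.random() >= config.separation:
                    others = [t for t in range(config.n_topics) if t != topic]
                    src = others[rng.integers(len(others))]
                else:
                    src = topic
                units.append(term_sets[src][rng.integers(config.terms_per_topic)])
        if n_bg:
            units.extend((background[j],) for j in rng.choice(
                config.background_vocab_size, size=n_bg, p=zipf))
        order = rng.permutation(len(units))
        tokens = [tok for u in order for tok in units[u]]
        messages.append(Message(id=f"m{i:05d}", author_id=author,
                                board_id="synthetic", timestamp=ts,
                                text=" ".join(tokens), gold_label=gold))
        truth.append(topic)

    entries = {
        term: frozenset({profile[t]})
        for t, terms in enumerate(term_sets) for term in terms
    }
    lexicon = Lexicon(entries, default_semantic_types())
    corpus = Corpus(messages=messages, board_name="synthetic",
                    disease_type="synthetic")
    return SyntheticCorpus(corpus=corpus, lexicon=lexicon, truth=truth,
                           topic_terms=[[" ".join(t) for t in s] for s in term_sets],
                           type_profile=profile)


def write_lexicon_tsv(lexicon: Lexicon, path) -> None:
    """Serialize a lexicon as ``term<TAB>type1|type2`` lines."""
    lines = [
        " ".join(term) + "\t" + "|".join(sorted(types))
        for term, types in sorted(lexicon.entries.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
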