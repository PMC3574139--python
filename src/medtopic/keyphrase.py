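"""Cluster key-phrase scoring and semantic-type-based topic labeling.

Candidate key phrases are the content n-grams (n = 1..3) plus matched
lexicon terms. A TF-IDF-like score ranks how characteristic a term w is of
cluster C_i:

    score(w, C_i) = f(w, C_i) * ln(N / n_w)

where f(w, C_i) is the frequency of w in the cluster, N the number of
clusters, and n_w the number of clusters whose frequency of w is greater
than or equal to f(w, C_i) — so an exclusive term scores f * ln N and a
term spread evenly over all clusters scores 0.

Clusters are then labeled by their dominant semantic type: sosy -> Symptom,
dsyn/patf -> Complication, diap/lbpr -> Examination, topp -> Procedure,
phsu -> Drug, anything else -> Other. Clusters sharing a label are reported
as mergeable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .features import _ngrams
from .lexicon import TermMatch
from .preprocess import TokenizedMessage

__all__ = [
    "TermClusterFrequency",
    "KeyPhraseScore",
    "TopicLabel",
    "TYPE_TO_CATEGORY",
    "term_cluster_frequencies",
    "score_keyphrases",
    "label_clusters",
    "mergeable_groups",
]

TYPE_TO_CATEGORY = {
    "sosy": "Symptom",
    "dsyn": "Complication",
    "patf": "Complication",
    "diap": "Examination",
    "lbpr": "Examination",
    "topp": "Procedure",
    "phsu": "Drug",
}
CATEGORIES = ("Symptom", "Complication", "Examination", "Procedure", "Drug", "Other")


@dataclass
class TermClusterFrequency:
    term: str
    freq: np.ndarray  # (N,) per-cluster occurrence counts

    @property
    def N(self) -> int:
        return len(self.freq)


@dataclass(frozen=True)
class KeyPhraseScore:
    term: str
    cluster_id: int
    f: int
    n_w: int
    score: float


@dataclass
class TopicLabel:
    cluster_id: int
    label: str
    dominant_types: list[str]
    top_phrases: list[str] = field(default_factory=list)


def term_cluster_frequencies(tokenized: Sequence[TokenizedMessage],
                             matches: Mapping[str, Sequence[TermMatch]],
                             hard_labels: Sequence[int],
                             n_clusters: Optional[int] = None,
                             doc_freq: bool = False) -> list[TermClusterFrequency]:
    """Per-cluster occurrence counts for every candidate term.

    Candidates are all content n-grams up to length 3 plus every matched
    lexicon term; terms that are both (a matched unigram, say) are counted
    once, via their n-gram occurrences. With ``doc_freq`` counts are
    distinct-message counts instead of token occurrences.
    """
    labels = np.asarray(hard_labels)
    if len(labels) != len(tokenized):
        raise ValueError("hard_labels do not align with tokenized messages")
    N = int(n_clusters) if n_clusters is not None else int(labels.max()) + 1
    counts: dict[str, np.ndarray] = {}

    def bump(term: str, cluster: int, amount: int) -> None:
        vec = counts.get(term)
        if vec is None:
            vec = counts[term] = np.zeros(N, dtype=np.int64)
        vec[cluster] += amount

    for tok, lab in zip(tokenized, labels):
        if not 0 <= lab < N:
            raise ValueError(f"label {lab} out of range for N={N}")
        per_msg: Counter[str] = Counter()
        for n in (1, 2, 3):
            per_msg.update(_ngrams(tok.content_tokens, n))
        ngram_set = set(per_msg)
        for m in matches.get(tok.message_id, ()):
            if m.term not in ngram_set:   # e.g. terms longer than 3 tokens
                per_msg[m.term] += 1
        for term, c in per_msg.items():
            bump(term, int(lab), 1 if doc_freq else c)
    return [TermClusterFrequency(term=t, freq=v) for t, v in sorted(counts.items())]


def score_keyphrases(freqs: Sequence[TermClusterFrequency],
                     top_m: int = 10) -> list[list[KeyPhraseScore]]:
    """Rank terms per cluster by score = f * ln(N / n_w).

    n_w counts clusters with frequency >= the evaluated cluster's, so
    n_w >= 1 always. Per-cluster lists are sorted by descending score with
    lexicographic tie-break, truncated to ``top_m``; zero-frequency terms
    never appear.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    if not freqs:
        return []
    N = freqs[0].N
    per_cluster: list[list[KeyPhraseScore]] = [[] for _ in range(N)]
    for tf in freqs:
        f = tf.freq
        order = np.sort(f)[::-1]
        for i in range(N):
            if f[i] == 0:
                continue
            n_w = int(np.searchsorted(-order, -f[i], side="right"))
            score = float(f[i]) * math.log(N / n_w)
            per_cluster[i].append(KeyPhraseScore(term=tf.term, cluster_id=i,
                                                 f=int(f[i]), n_w=n_w, score=score))
    for i in range(N):
        per_cluster[i].sort(key=lambda s: (-s.score, s.term))
        del per_cluster[i][top_m:]
    return per_cluster


def label_clusters(hard_labels: Sequence[int],
                   sem_type_counts: np.ndarray,
                   sem_type_names: Sequence[str],
                   scores: Optional[Sequence[Sequence[KeyPhraseScore]]] = None,
                   n_clusters: Optional[int] = None) -> list[TopicLabel]:
    """Assign each cluster a topic category from its dominant semantic type.

    ``sem_type_counts`` is the per-message semantic-type count block
    (n_messages x n_types, columns ordered as ``sem_type_names``). Types are
    ranked by summed counts over the cluster's members; the top type maps
    through ``TYPE_TO_CATEGORY``, and a cluster with no semantic-type
    counts — or a top type outside the mapping — is labeled Other.
    """
    labels = np.asarray(hard_labels)
    counts = np.asarray(sem_type_counts)
    if counts.shape[0] != len(labels):
        raise ValueError("sem_type_counts rows do not align with hard_labels")
    N = int(n_clusters) if n_clusters is not None else int(labels.max()) + 1
    out: list[TopicLabel] = []
    for i in range(N):
        member = counts[labels == i]
        totals = member.sum(axis=0) if member.size else np.zeros(counts.shape[1])
        ranked = sorted(
            ((sem_type_names[j], totals[j]) for j in range(len(sem_type_names))
             if totals[j] > 0),
            key=lambda p: (-p[1], p[0]),
        )
        dominant = [name for name, _ in ranked]
        label = TYPE_TO_CATEGORY.get(dominant[0], "Other") if dominant else "Other"
        phrases = [s.term for s in scores[i]] if scores is not None else []
        out.append(TopicLabel(cluster_id=i, label=label,
                              dominant_types=dominant, top_phrases=phrases))
    return out


def mergeable_groups(topic_labels: Sequence[TopicLabel]) -> dict[str, list[int]]:
    """Clusters that share a category (candidates for merging)."""
    groups: dict[str, list[int]] = {}
    for tl in topic_labels:
        groups.setdefault(tl.label, []).append(tl.cluster_id)
    return {lab: ids for lab, ids in groups.items() if len(ids) > 1}
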