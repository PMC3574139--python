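"""External cluster validation and inter-annotator agreement.

Clustering quality against a gold labeling is measured by pair counting:
over all n(n-1)/2 unordered message pairs, SS/SD/DS/DD count agreement and
disagreement of cluster membership (first letter) vs gold category
membership (second letter). SS and DD are good choices, SD and DS bad. The
derived indices:

    Rand    = (SS + DD) / (SS + SD + DS + DD)
    Jaccard = SS / (SS + SD + DS)
    FM      = SS / sqrt((SS + SD) * (SS + DS))

Jaccard and FM are defined as 0 when their denominators vanish. Agreement
between two annotators' nominal labelings is measured by unweighted
Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

__all__ = [
    "PairCounts",
    "ExternalIndices",
    "KappaResult",
    "pair_counts",
    "external_indices",
    "cohens_kappa",
]


@dataclass(frozen=True)
class PairCounts:
    SS: int
    SD: int
    DS: int
    DD: int

    @property
    def total(self) -> int:
        return self.SS + self.SD + self.DS + self.DD


@dataclass(frozen=True)
class ExternalIndices:
    rand: float
    jaccard: float
    fm: float


@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: float


def _contingency(a: Sequence, b: Sequence) -> np.ndarray:
    _, ai = np.unique(np.asarray(a), return_inverse=True)
    _, bi = np.unique(np.asarray(b), return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def pair_counts(pred_labels: Sequence, true_labels: Sequence) -> PairCounts:
    """SS/SD/DS/DD over all unordered pairs, via contingency-table algebra.

    "Same cluster" refers to ``pred_labels``; "same category" to
    ``true_labels``. Equivalent to brute-force pair enumeration.
    """
    if len(pred_labels) != len(true_labels):
        raise ValueError("label vectors differ in length")
    n = len(pred_labels)
    if n < 2:
        raise ValueError("need at least 2 items to count pairs")
    table = _contingency(pred_labels, true_labels)

    def pairs(x: np.ndarray) -> int:
        return int((x * (x - 1) // 2).sum())

    ss = pairs(table)
    sd = pairs(table.sum(axis=1)) - ss     # same cluster, different category
    ds = pairs(table.sum(axis=0)) - ss     # different cluster, same category
    dd = n * (n - 1) // 2 - ss - sd - ds
    return PairCounts(SS=ss, SD=sd, DS=ds, DD=dd)


def external_indices(counts: PairCounts) -> ExternalIndices:
    """Rand, Jaccard and Fowlkes-Mallows from pair counts."""
    if counts.total <= 0:
        raise ValueError("no pairs to evaluate")
    rand = (counts.SS + counts.DD) / counts.total
    denom_j = counts.SS + counts.SD + counts.DS
    jaccard = counts.SS / denom_j if denom_j > 0 else 0.0
    denom_fm = (counts.SS + counts.SD) * (counts.SS + counts.DS)
    fm = counts.SS / sqrt(denom_fm) if denom_fm > 0 else 0.0
    return ExternalIndices(rand=rand, jaccard=jaccard, fm=fm)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> KappaResult:
    """Unweighted Cohen's kappa between two nominal labelings.

    p_o is the fraction of identical labels; p_e the chance agreement from
    the annotators' marginals. When p_e = 1 (both annotators constant on
    the same label), kappa is defined as 1 if agreement is perfect, else 0.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    n = len(labels_a)
    if n < 1:
        raise ValueError("need at least one item")
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    p_o = float(np.mean(a == b))
    cats = np.unique(np.concatenate([a, b]))
    p_e = float(sum(np.mean(a == c) * np.mean(b == c) for c in cats))
    if p_e >= 1.0:
        kappa = 1.0 if p_o >= 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(p_o=p_o, p_e=p_e, kappa=kappa)
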