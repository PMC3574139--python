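"""Reproducible validation experiments for the pipeline's core claims.

Each function builds its own inputs (published board statistics, simulated
Gaussian mixtures, or synthetic corpora), runs the package, and returns
measured quantities. All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np

from .corpus_io import Corpus, Message, corpus_stats
from .em_cluster import EMConfig, fit_em, select_k_cv
from .evaluate import PairCounts, external_indices, pair_counts
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import SyntheticConfig, generate_corpus

__all__ = [
    "STUDY_BOARD_COUNTS",
    "board_ratio",
    "em_monotonicity",
    "pair_counting_agreement",
    "blob_k_recovery",
    "end_to_end_recovery",
    "ablation_direction",
]

# Published per-board collection statistics (messages, distinct members)
# for the three disease discussion boards the method was demonstrated on.
STUDY_BOARD_COUNTS = {
    "lung_cancer": (4728, 1928),
    "breast_cancer": (65856, 16100),
    "diabetes": (25509, 8169),
}


def board_ratio(board: str) -> float:
    """Messages-per-member for a study board, computed by building a corpus
    with the published counts and summarizing it."""
    n_messages, n_members = STUDY_BOARD_COUNTS[board]
    messages = [
        Message(id=f"m{i}", author_id=f"u{i % n_members}", text="x")
        for i in range(n_messages)
    ]
    return corpus_stats(Corpus(messages=messages)).messages_per_member


def em_monotonicity(n_datasets: int = 50, seed: int = 0,
                    slack: float = 1e-9) -> dict:
    """Fit EM on random mixture datasets; check every log-likelihood trace
    is non-decreasing (the iterative-refinement guarantee)."""
    rng = np.random.default_rng(seed)
    monotone = 0
    worst = 0.0
    for trial in range(n_datasets):
        K = int(rng.integers(1, 5))
        true_k = int(rng.integers(1, 4))
        centers = rng.normal(scale=4.0, size=(true_k, 2))
        X = np.concatenate([
            rng.normal(centers[j], 1.0, size=(30, 2)) for j in range(true_k)])
        model, _ = fit_em(X, K, EMConfig(seed=int(rng.integers(2 ** 31))))
        diffs = np.diff(model.loglik_trace)
        violation = float(-diffs.min()) if len(diffs) else 0.0
        worst = max(worst, violation)
        monotone += violation <= slack
    return {"fraction_monotone": monotone / n_datasets,
            "worst_violation": worst, "n": n_datasets}


def _brute_force_counts(pred, true) -> PairCounts:
    ss = sd = ds = dd = 0
    for i, j in combinations(range(len(pred)), 2):
        same_c, same_t = pred[i] == pred[j], true[i] == true[j]
        if same_c and same_t:
            ss += 1
        elif same_c:
            sd += 1
        elif same_t:
            ds += 1
        else:
            dd += 1
    return PairCounts(ss, sd, ds, dd)


def pair_counting_agreement(n_trials: int = 200, seed: int = 0) -> dict:
    """Contingency-algebra pair counts vs brute-force enumeration on random
    labelings, plus the derived indices vs their defining ratios."""
    rng = np.random.default_rng(seed)
    count_ok = index_ok = 0
    for _ in range(n_trials):
        n = int(rng.integers(2, 51))
        pred = rng.integers(0, rng.integers(1, 6) + 1, n)
        true = rng.integers(0, rng.integers(1, 6) + 1, n)
        c = pair_counts(pred, true)
        count_ok += c == _brute_force_counts(list(pred), list(true))
        idx = external_indices(c)
        rand = (c.SS + c.DD) / c.total
        jac = c.SS / (c.SS + c.SD + c.DS) if c.SS + c.SD + c.DS else 0.0
        denom = (c.SS + c.SD) * (c.SS + c.DS)
        fm = c.SS / np.sqrt(denom) if denom else 0.0
        index_ok += (abs(idx.rand - rand) < 1e-12
                     and abs(idx.jaccard - jac) < 1e-12
                     and abs(idx.fm - fm) < 1e-12)
    return {"fraction_counts_equal": count_ok / n_trials,
            "fraction_indices_equal": index_ok / n_trials, "n": n_trials}


def blob_k_recovery(n_seeds: int = 10, seed: int = 0) -> dict:
    """Cross-validated K selection on three well-separated 1-D Gaussian
    blobs (means 0/10/20, std 0.5, 60 points each)."""
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + i)
        X = np.concatenate([
            rng.normal(c, 0.5, 60) for c in (0.0, 10.0, 20.0)])[:, None]
        best, _ = select_k_cv(X, EMConfig(seed=seed * 1000 + i, k_max=6))
        hits += best == 3
    return {"recovery_rate": hits / n_seeds, "n": n_seeds}


def end_to_end_recovery(n_seeds: int = 10, seed: int = 0,
                        n_messages: int = 2000) -> dict:
    """Full pipeline on synthetic corpora (K cycling 3/4/5): is the
    cross-validated K correct and the Rand index vs ground truth >= 0.9?"""
    successes = 0
    k_correct = 0
    rands = []
    for i in range(n_seeds):
        true_k = [3, 4, 5][i % 3]
        s = (seed * 1000 + i) % (2 ** 31)
        syn = generate_corpus(SyntheticConfig(
            n_topics=true_k, n_messages=n_messages, seed=s))
        rep = run_pipeline(
            PipelineConfig(seed=s, em=EMConfig(seed=s, k_max=10)),
            corpus=syn.corpus, lexicon=syn.lexicon)
        rand = rep.evaluation["rand"]
        rands.append(rand)
        k_correct += rep.chosen_k == true_k
        successes += (rep.chosen_k == true_k) and rand >= 0.9
    return {"success_rate": successes / n_seeds,
            "k_accuracy": k_correct / n_seeds,
            "rand_mean": float(np.mean(rands)), "n": n_seeds}


def ablation_direction(n_seeds: int = 10, seed: int = 0,
                       n_messages: int = 1000) -> dict:
    """Keyword-only (F1) vs combined (F1+F2) clustering at the true K:
    how often does adding the medical blocks not hurt the Rand index?"""
    wins = 0
    rand_f1, rand_both = [], []
    for i in range(n_seeds):
        true_k = [3, 4, 5][i % 3]
        s = (seed * 1000 + i) % (2 ** 31)
        syn = generate_corpus(SyntheticConfig(
            n_topics=true_k, n_messages=n_messages, seed=s))
        rands = {}
        for blocks in ("F1", "F1+F2"):
            rep = run_pipeline(
                PipelineConfig(seed=s, feature_blocks=blocks, k=true_k,
                               em=EMConfig(seed=s)),
                corpus=syn.corpus, lexicon=syn.lexicon)
            rands[blocks] = rep.evaluation["rand"]
        rand_f1.append(rands["F1"])
        rand_both.append(rands["F1+F2"])
        wins += rands["F1+F2"] >= rands["F1"]
    return {"win_fraction": wins / n_seeds,
            "rand_f1_mean": float(np.mean(rand_f1)),
            "rand_f1f2_mean": float(np.mean(rand_both)), "n": n_seeds}
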