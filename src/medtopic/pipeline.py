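"""End-to-end topic-detection runs: read -> preprocess -> match ->
featurize -> PCA -> cluster -> key-phrase -> label -> evaluate.

Stages run in a fixed order matching the three phases of the method —
data preparation, feature-set generation, clustering and topic
identification — with evaluation appended when gold labels are present.
All randomness flows from one seed; rerunning with the same config and
seed reproduces every numeric field of the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .corpus_io import Corpus, corpus_stats, read_corpus
from .em_cluster import EMConfig, fit_em, save_model, select_k_cv
from .evaluate import cohens_kappa, external_indices, pair_counts
from .features import (F1_BLOCKS, F2_BLOCKS, BLOCKS, build_vocabulary,
                       match_corpus, select_blocks, vectorize)
from .keyphrase import (CATEGORIES, label_clusters, mergeable_groups,
                        score_keyphrases, term_cluster_frequencies)
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .pca_reduce import fit_pca, save_pca, transform
from .preprocess import (PreprocessConfig, default_stoplist,
                         filter_noise_messages, load_stoplist,
                         tokenize_corpus)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

_BLOCK_SETS = {
    "F1": F1_BLOCKS,
    "F2": F2_BLOCKS,
    "F1+F2": F1_BLOCKS | F2_BLOCKS,
}


@dataclass
class PipelineConfig:
    corpus_path: Optional[str] = None
    lexicon_path: Optional[str] = None
    stoplist_path: Optional[str] = None
    output_dir: Optional[str] = None
    feature_blocks: str = "F1+F2"
    min_df: int = 3
    length_normalize: bool = True
    coverage_target: float = 0.95
    pca_selection: str = "elbow"
    # Component stds are floored at this fraction of the reduced data's
    # global std: standard mixture-model variance flooring, preventing
    # components from specializing on count-lattice clumps.
    variance_floor_frac: float = 0.2
    k: Optional[int] = None          # fixed cluster count; None -> CV selection
    top_m: int = 10
    keyphrase_doc_freq: bool = False
    seed: int = 0
    preprocess: Optional[PreprocessConfig] = None
    em: EMConfig = field(default_factory=EMConfig)

    def __post_init__(self):
        if self.feature_blocks not in _BLOCK_SETS:
            raise ValueError(
                f"feature_blocks must be one of {sorted(_BLOCK_SETS)}")


@dataclass
class RunReport:
    seed: int
    feature_blocks: str
    corpus_stats: dict
    n_messages_raw: int
    n_messages_filtered: int
    n_features: dict
    n_components: int
    chosen_k: int
    cv_curve: Optional[list[float]]
    final_loglik: float
    n_iterations: int
    converged: bool
    cluster_labels: list[dict]
    mergeable: dict
    keyphrases: list[list[dict]]
    evaluation: Optional[dict]
    config: dict
    version: str

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig,
                 corpus: Optional[Corpus] = None,
                 lexicon: Optional[Lexicon] = None) -> RunReport:
    """Execute the full pipeline and return a serializable report.

    ``corpus``/``lexicon`` may be passed in memory; otherwise they are read
    from the configured paths (falling back to the packaged toy lexicon).
    Stage errors propagate with the stage name prefixed.
    """
    stage = "read"
    try:
        if corpus is None:
            if config.corpus_path is None:
                raise ValueError("no corpus given (corpus_path unset)")
            corpus = read_corpus(config.corpus_path)
        corpus.validate()
        if lexicon is None:
            lexicon = (load_lexicon(config.lexicon_path)
                       if config.lexicon_path else default_lexicon())
        stats = corpus_stats(corpus) if len(corpus) else None
        logger.info("read: %d messages, lexicon of %d terms", len(corpus), len(lexicon))

        stage = "preprocess"
        pre = config.preprocess
        if pre is None:
            stoplist = (load_stoplist(config.stoplist_path)
                        if config.stoplist_path else default_stoplist())
            pre = PreprocessConfig(stoplist=stoplist)
        tokenized = tokenize_corpus(corpus, pre)

        stage = "noise_filter"
        filtered = filter_noise_messages(corpus, tokenized, lexicon, pre)
        by_id = {t.message_id: t for t in tokenized}
        tokenized_f = [by_id[m.id] for m in filtered]
        if not tokenized_f:
            raise ValueError("no messages survive noise filtering")
        logger.info("noise_filter: %d -> %d messages", len(corpus), len(filtered))

        stage = "features"
        matches = match_corpus(tokenized_f, lexicon)
        vocab = build_vocabulary(tokenized_f, matches, min_df=config.min_df)
        full = vectorize(tokenized_f, matches, vocab,
                         length_normalize=config.length_normalize)
        selected = select_blocks(full, _BLOCK_SETS[config.feature_blocks])
        n_features = {b: len(vocab._block_lists()[BLOCKS.index(b)]) for b in BLOCKS}
        logger.info("features: %s columns by block", n_features)

        stage = "pca"
        pca = fit_pca(selected, coverage_target=config.coverage_target,
                      selection=config.pca_selection)
        X = transform(pca, selected)
        logger.info("pca: %d -> %d dimensions", selected.shape[1], X.shape[1])

        stage = "cluster"
        floor = max(config.em.min_std,
                    config.variance_floor_frac * float(X.std()))
        em = replace(config.em, seed=config.seed, min_std=floor)
        cv_curve = None
        if config.k is None:
            chosen_k, cv_curve = select_k_cv(X, em)
            logger.info("cluster: cross-validation chose K=%d", chosen_k)
        else:
            chosen_k = config.k
        model, assignment = fit_em(X, chosen_k, em)

        stage = "keyphrase"
        freqs = term_cluster_frequencies(tokenized_f, matches,
                                         assignment.hard_labels,
                                         n_clusters=chosen_k,
                                         doc_freq=config.keyphrase_doc_freq)
        scores = score_keyphrases(freqs, top_m=config.top_m)
        sem_block = full.values[:, full.vocabulary.block_slice("sem_type")]
        labels = label_clusters(assignment.hard_labels, sem_block,
                                full.vocabulary.sem_types, scores,
                                n_clusters=chosen_k)

        stage = "evaluate"
        evaluation = None
        gold = [m.gold_label for m in filtered]
        has_gold = [i for i, g in enumerate(gold) if g is not None]
        if has_gold:
            true = [gold[i] for i in has_gold]
            pred = [int(assignment.hard_labels[i]) for i in has_gold]
            counts = pair_counts(pred, true)
            idx = external_indices(counts)
            evaluation = {
                "n_evaluated": len(has_gold),
                "pair_counts": asdict(counts),
                "rand": idx.rand, "jaccard": idx.jaccard, "fm": idx.fm,
            }
            if set(true) <= set(CATEGORIES):
                pred_cat = [labels[p].label for p in pred]
                evaluation["kappa"] = asdict(cohens_kappa(pred_cat, true))
            logger.info("evaluate: rand=%.3f jaccard=%.3f fm=%.3f",
                        idx.rand, idx.jaccard, idx.fm)
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    report = RunReport(
        seed=config.seed,
        feature_blocks=config.feature_blocks,
        corpus_stats={
            "n_messages": stats.n_messages,
            "n_members": stats.n_members,
            "messages_per_member": stats.messages_per_member,
            "time_span": [str(t) for t in stats.time_span] if stats.time_span else None,
        } if stats else {},
        n_messages_raw=len(corpus),
        n_messages_filtered=len(filtered),
        n_features=n_features,
        n_components=X.shape[1],
        chosen_k=chosen_k,
        cv_curve=cv_curve,
        final_loglik=model.loglik_trace[-1],
        n_iterations=len(model.loglik_trace),
        converged=model.converged,
        cluster_labels=[asdict(t) for t in labels],
        mergeable=mergeable_groups(labels),
        keyphrases=[[asdict(s) for s in cl] for cl in scores],
        evaluation=evaluation,
        config={
            "feature_blocks": config.feature_blocks, "min_df": config.min_df,
            "coverage_target": config.coverage_target,
            "pca_selection": config.pca_selection,
            "length_normalize": config.length_normalize, "k": config.k,
            "top_m": config.top_m, "seed": config.seed,
            "em": asdict(em),
        },
        version=__version__,
    )
    if config.output_dir:
        write_report(report, config.output_dir, model=model, pca=pca)
    return report


def write_report(report: RunReport, output_dir,
                 model=None, pca=None) -> None:
    """Write report.json, keyphrases.tsv and model/pca JSON to a run dir."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2), encoding="utf-8")
    lines = ["cluster\trank\tterm\tf\tn_w\tscore"]
    for i, cl in enumerate(report.keyphrases):
        for rank, s in enumerate(cl, 1):
            lines.append(f"{i}\t{rank}\t{s['term']}\t{s['f']}\t{s['n_w']}\t{s['score']:.4f}")
    (out / "keyphrases.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if model is not None:
        save_model(model, out / "model.json")
    if pca is not None:
        save_pca(pca, out / "pca.json")
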