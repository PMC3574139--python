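"""Key-phrase scoring and semantic-type cluster labeling."""

import math

import numpy as np
import pytest

from medtopic.features import match_corpus
from medtopic.keyphrase import (KeyPhraseScore, TermClusterFrequency,
                                label_clusters, mergeable_groups,
                                score_keyphrases, term_cluster_frequencies)
from medtopic.preprocess import TokenizedMessage


def tmsg(i, tokens):
    return TokenizedMessage(message_id=f"m{i}", raw_tokens=tuple(tokens),
                            content_tokens=tuple(tokens))


def tf(term, freq):
    return TermClusterFrequency(term=term, freq=np.asarray(freq))


class TestFrequencies:
    def test_single_cluster_occurrence(self):
        toks = [tmsg(0, ["pain"]), tmsg(1, ["x"]), tmsg(2, ["y"])]
        freqs = term_cluster_frequencies(toks, {}, [0, 1, 2], n_clusters=3)
        by_term = {f.term: f.freq for f in freqs}
        assert list(by_term["pain"]) == [1, 0, 0]

    def test_relabeling_equivariance(self):
        toks = [tmsg(0, ["a", "b"]), tmsg(1, ["a"]), tmsg(2, ["b", "b"])]
        f01 = {f.term: f.freq for f in
               term_cluster_frequencies(toks, {}, [0, 0, 1], n_clusters=2)}
        f10 = {f.term: f.freq for f in
               term_cluster_frequencies(toks, {}, [1, 1, 0], n_clusters=2)}
        for term in f01:
            assert list(f01[term]) == list(f10[term][::-1])

    def test_counts_match_brute_force(self, tiny_lexicon):
        toks = [tmsg(0, ["chest", "pain", "pain"]), tmsg(1, ["chemo"]),
                tmsg(2, ["pain", "chemo"]), tmsg(3, ["x", "y", "x"]),
                tmsg(4, ["chest", "pain"]), tmsg(5, ["y"])]
        matches = match_corpus(toks, tiny_lexicon)
        labels = [0, 0, 1, 1, 0, 1]
        freqs = {f.term: f.freq for f in
                 term_cluster_frequencies(toks, matches, labels, n_clusters=2)}
        # brute-force tallies of unigram occurrences
        # pain: 2 in msg0 + 1 in msg4 (cluster 0), 1 in msg2 (cluster 1)
        assert list(freqs["pain"]) == [3, 1]
        # chemo: msg1 is in cluster 0, msg2 in cluster 1
        assert list(freqs["chemo"]) == [1, 1]
        assert list(freqs["x"]) == [0, 2]
        # bigram present
        assert list(freqs["chest pain"]) == [2, 0]

    def test_label_mismatch_error(self):
        with pytest.raises(ValueError):
            term_cluster_frequencies([tmsg(0, ["a"])], {}, [0, 1])


class TestScores:
    def test_exclusive_term_scores_f_log_n(self):
        scores = score_keyphrases([tf("w", [5, 0, 0])], top_m=5)
        s = scores[0][0]
        assert s.n_w == 1
        assert s.score == pytest.approx(5 * math.log(3))
        assert scores[1] == [] and scores[2] == []

    def test_uniform_term_scores_zero(self):
        scores = score_keyphrases([tf("w", [2, 2, 2])], top_m=5)
        for cl in scores:
            assert cl[0].score == 0.0 and cl[0].n_w == 3

    def test_worked_422_fixture(self):
        scores = score_keyphrases([tf("w", [4, 2, 2])], top_m=5)
        assert scores[0][0].n_w == 1
        assert scores[0][0].score == pytest.approx(4 * math.log(3))
        assert scores[1][0].n_w == 3 and scores[1][0].score == 0.0
        assert scores[2][0].score == 0.0

    def test_score_monotone_in_f_for_fixed_nw(self):
        lo = score_keyphrases([tf("w", [2, 0])], top_m=1)[0][0]
        hi = score_keyphrases([tf("w", [7, 0])], top_m=1)[0][0]
        assert lo.n_w == hi.n_w == 1 and hi.score > lo.score

    def test_ranking_and_truncation(self):
        freqs = [tf("alpha", [3, 0]), tf("beta", [3, 0]), tf("gamma", [9, 0]),
                 tf("delta", [1, 1])]
        scores = score_keyphrases(freqs, top_m=3)
        assert [s.term for s in scores[0]] == ["gamma", "alpha", "beta"]

    def test_bad_top_m(self):
        with pytest.raises(ValueError):
            score_keyphrases([tf("w", [1])], top_m=0)


class TestLabels:
    types = ["diap", "dsyn", "lbpr", "patf", "phsu", "sosy", "topp"]

    def counts_for(self, per_cluster_type, labels):
        X = np.zeros((len(labels), len(self.types)))
        for i, lab in enumerate(labels):
            for t, c in per_cluster_type[lab].items():
                X[i, self.types.index(t)] = c
        return X

    @pytest.mark.parametrize("abbrev,category", [
        ("sosy", "Symptom"), ("dsyn", "Complication"), ("patf", "Complication"),
        ("diap", "Examination"), ("lbpr", "Examination"),
        ("topp", "Procedure"), ("phsu", "Drug"),
    ])
    def test_dominant_type_maps_to_category(self, abbrev, category):
        labels = [0, 0]
        X = self.counts_for([{abbrev: 4, "sosy" if abbrev != "sosy" else "topp": 1}],
                            labels)
        (tl,) = label_clusters(labels, X, self.types)
        assert tl.label == category
        assert tl.dominant_types[0] == abbrev

    def test_combined_dsyn_patf_complication(self):
        labels = [0, 0, 0]
        X = self.counts_for([{"dsyn": 3, "patf": 2, "sosy": 4}], labels)
        (tl,) = label_clusters(labels, X, self.types)
        # sosy leads individually, but dsyn+patf jointly dominate; top single
        # type still decides — construct the complication-dominant case:
        X2 = self.counts_for([{"dsyn": 5, "patf": 4, "sosy": 4}], labels)
        (tl2,) = label_clusters(labels, X2, self.types)
        assert tl2.label == "Complication"

    def test_zero_counts_cluster_is_other(self):
        labels = [0, 1]
        X = self.counts_for([{"sosy": 2}, {}], labels)
        tls = label_clusters(labels, X, self.types)
        assert tls[0].label == "Symptom" and tls[1].label == "Other"
        assert tls[1].dominant_types == []

    def test_every_cluster_gets_one_label_and_merge_report(self):
        labels = [0, 1, 2]
        X = self.counts_for([{"sosy": 2}, {"sosy": 3}, {"phsu": 1}], labels)
        tls = label_clusters(labels, X, self.types)
        assert [t.label for t in tls] == ["Symptom", "Symptom", "Drug"]
        assert mergeable_groups(tls) == {"Symptom": [0, 1]}
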