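"""Pair-counting external validation and Cohen's kappa."""

from itertools import combinations
from math import sqrt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score
from sklearn.metrics.cluster import pair_confusion_matrix

from medtopic.evaluate import (PairCounts, cohens_kappa, external_indices,
                               pair_counts)


def brute_force_counts(pred, true):
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


class TestPairCounts:
    def test_worked_example(self):
        c = pair_counts([1, 1, 2, 2], [1, 1, 1, 2])
        assert (c.SS, c.SD, c.DS, c.DD) == (1, 1, 2, 2)

    def test_identical_labelings(self):
        c = pair_counts(["a", "a", "b"], ["x", "x", "y"])
        assert c.SD == 0 and c.DS == 0

    def test_singletons_vs_one_class(self):
        c = pair_counts([1, 2, 3, 4], [0, 0, 0, 0])
        assert c.SS == 0 and c.SD == 0
        assert c.DS == 6 and c.DD == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            pair_counts([1, 2], [1])
        with pytest.raises(ValueError):
            pair_counts([1], [1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 50), st.integers(0, 10 ** 6))
    def test_contingency_equals_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 5, n)
        true = rng.integers(0, 4, n)
        c = pair_counts(pred, true)
        assert c == brute_force_counts(list(pred), list(true))
        assert c.total == n * (n - 1) // 2

    def test_matches_sklearn_pair_confusion(self):
        rng = np.random.default_rng(17)
        pred, true = rng.integers(0, 4, 100), rng.integers(0, 3, 100)
        c = pair_counts(pred, true)
        M = pair_confusion_matrix(true, pred)  # ordered pairs, doubled
        assert c.SS == M[1, 1] // 2 and c.DD == M[0, 0] // 2
        assert c.SD == M[0, 1] // 2 and c.DS == M[1, 0] // 2


class TestIndices:
    def test_worked_example(self):
        idx = external_indices(PairCounts(1, 1, 2, 2))
        assert idx.rand == pytest.approx(0.5)
        assert idx.jaccard == pytest.approx(0.25)
        assert idx.fm == pytest.approx(1 / sqrt(6))

    def test_perfect_clustering(self):
        idx = external_indices(PairCounts(SS=10, SD=0, DS=0, DD=5))
        assert idx.rand == idx.jaccard == idx.fm == 1.0

    def test_zero_ss_convention(self):
        idx = external_indices(PairCounts(SS=0, SD=2, DS=3, DD=1))
        assert idx.jaccard == 0.0 and idx.fm == 0.0

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            external_indices(PairCounts(0, 0, 0, 0))

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(23)
        pred, true = rng.integers(0, 3, 60), rng.integers(0, 3, 60)
        a = external_indices(pair_counts(pred, true))
        remap = {0: 7, 1: 3, 2: 5}
        b = external_indices(pair_counts([remap[p] for p in pred], true))
        assert a == b

    def test_rand_one_iff_same_partition(self):
        assert external_indices(pair_counts([0, 0, 1], [5, 5, 9])).rand == 1.0
        assert external_indices(pair_counts([0, 1, 1], [5, 5, 9])).rand < 1.0


class TestKappa:
    def test_identical_vectors(self):
        assert cohens_kappa(["x", "y", "x"], ["x", "y", "x"]).kappa == 1.0

    def test_worked_example_zero_kappa(self):
        r = cohens_kappa(list("xxyy"), list("xyxy"))
        assert r.p_o == 0.5 and r.p_e == 0.5 and r.kappa == 0.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(31)
        a = rng.integers(0, 4, 200)
        b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 4, 200))
        assert cohens_kappa(a, b).kappa == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)

    def test_independent_labels_near_zero(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.integers(0, 3, 1000)
            b = rng.integers(0, 3, 1000)
            assert abs(cohens_kappa(a, b).kappa) < 0.1

    def test_degenerate_constant_annotators(self):
        assert cohens_kappa(["x", "x"], ["x", "x"]).kappa == 1.0

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            cohens_kappa([1], [1, 2])
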