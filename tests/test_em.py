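"""Diagonal-Gaussian mixture EM: E/M updates against brute-force density
computation, likelihood monotonicity, parameter recovery, and
cross-validated selection of the cluster count."""

import numpy as np
import pytest
from scipy import stats
from sklearn.mixture import GaussianMixture

from medtopic.em_cluster import (ClusterAssignment, EMConfig, MixtureModel,
                                 e_step, fit_em, load_model, m_step,
                                 save_model, select_k_cv, total_loglik)


def model_1d(weights, means, stds):
    return MixtureModel(K=len(weights), weights=np.asarray(weights, float),
                        means=np.asarray(means, float)[:, None],
                        stds=np.asarray(stds, float)[:, None])


class TestEStep:
    def test_single_component_gives_unit_responsibility(self):
        X = np.array([[0.0], [3.0], [-1.0]])
        a = e_step(model_1d([1.0], [0.0], [1.0]), X)
        assert np.all(a.responsibilities == 1.0)

    def test_symmetric_point_splits_evenly(self):
        m = model_1d([0.5, 0.5], [-2.0, 2.0], [1.0, 1.0])
        a = e_step(m, np.array([[0.0]]))
        assert np.allclose(a.responsibilities, [[0.5, 0.5]], atol=1e-12)

    def test_matches_brute_force_densities(self):
        """Independent oracle: normalized weighted normal pdfs via scipy."""
        m = model_1d([0.3, 0.7], [-1.0, 2.0], [0.5, 1.5])
        X = np.array([[-1.2], [0.4], [2.5]])
        a = e_step(m, X)
        for i, x in enumerate(X[:, 0]):
            joint = np.array([
                w * stats.norm.pdf(x, mu, sd)
                for w, mu, sd in zip(m.weights, m.means[:, 0], m.stds[:, 0])])
            assert np.allclose(a.responsibilities[i], joint / joint.sum(),
                               atol=1e-12)

    def test_rows_normalized(self):
        rng = np.random.default_rng(0)
        m = MixtureModel(K=3, weights=np.array([0.2, 0.5, 0.3]),
                         means=rng.normal(size=(3, 4)),
                         stds=np.full((3, 4), 1.3))
        a = e_step(m, rng.normal(size=(40, 4)))
        assert np.allclose(a.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((a.responsibilities >= 0) & (a.responsibilities <= 1))

    def test_non_finite_input_error(self):
        with pytest.raises(ValueError):
            e_step(model_1d([1.0], [0.0], [1.0]), np.array([[np.nan]]))


class TestMStep:
    def test_hard_responsibilities_give_group_statistics(self):
        X = np.array([[0.0], [2.0], [10.0], [14.0]])
        R = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        m = m_step(ClusterAssignment(R, R.argmax(1)), X)
        assert np.allclose(m.weights, [0.5, 0.5])
        assert np.allclose(m.means[:, 0], [1.0, 12.0])
        assert np.allclose(m.stds[:, 0], [1.0, 2.0])  # population std

    def test_uniform_responsibilities_give_global_statistics(self):
        X = np.array([[1.0], [3.0], [5.0]])
        R = np.full((3, 2), 0.5)
        m = m_step(ClusterAssignment(R, R.argmax(1)), X)
        assert np.allclose(m.means, X.mean())
        assert np.allclose(m.stds, X.std())
        assert np.allclose(m.weights, 0.5)

    def test_fractional_responsibilities_weighted_statistics(self):
        """4-point fixture against hand-computed weighted mean/variance."""
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        R = np.array([[0.9, 0.1], [0.6, 0.4], [0.3, 0.7], [0.1, 0.9]])
        m = m_step(ClusterAssignment(R, R.argmax(1)), X)
        for k in range(2):
            w = R[:, k]
            mean = (w * X[:, 0]).sum() / w.sum()
            var = (w * (X[:, 0] - mean) ** 2).sum() / w.sum()
            assert m.weights[k] == pytest.approx(w.sum() / 4)
            assert m.means[k, 0] == pytest.approx(mean)
            assert m.stds[k, 0] == pytest.approx(np.sqrt(var))

    def test_std_floor_applies(self):
        X = np.array([[1.0], [1.0]])
        R = np.ones((2, 1))
        m = m_step(ClusterAssignment(R, R.argmax(1)), X,
                   EMConfig(min_std=1e-3))
        assert m.stds[0, 0] == 1e-3

    def test_empty_component_reinitialized(self):
        X = np.array([[0.0], [1.0], [2.0]])
        R = np.column_stack([np.ones(3), np.zeros(3)])
        m = m_step(ClusterAssignment(R, R.argmax(1)), X, EMConfig(seed=1),
                   rng=np.random.default_rng(1))
        assert np.all(m.weights > 0)


class TestFitEM:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.normal(2.0, 1.5, size=(200, 1))
        model, _ = fit_em(X, 1, EMConfig(seed=0))
        expected = stats.norm.logpdf(X[:, 0], X.mean(), X.std()).sum()
        assert model.loglik_trace[-1] == pytest.approx(expected, abs=1e-6)
        assert model.converged

    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-10, 0.5, 100),
                            rng.normal(10, 0.5, 100)])[:, None]
        truth = np.repeat([0, 1], 100)
        model, a = fit_em(X, 2, EMConfig(seed=3))
        same = (a.hard_labels == truth).mean()
        assert same in (0.0, 1.0)  # exact up to label permutation
        means = np.sort(model.means[:, 0])
        se = 0.5 / np.sqrt(100)
        assert abs(means[0] + 10) < 3 * se and abs(means[1] - 10) < 3 * se

    def test_identical_rows_get_identical_responsibilities(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(size=(20, 2))] * 2)
        _, a = fit_em(X, 3, EMConfig(seed=4))
        assert np.allclose(a.responsibilities[:20], a.responsibilities[20:],
                           atol=1e-12)

    def test_k_exceeding_rows_error(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 1)), 4, EMConfig())

    def test_one_iteration_matches_hand_computed_update(self):
        """Tiny fixture: one E+M cycle equals direct computation to 1e-10."""
        X = np.array([[-1.0], [0.5], [2.0]])
        m0 = model_1d([0.4, 0.6], [-1.0, 1.0], [1.0, 2.0])
        a = e_step(m0, X)
        joint = np.array([
            [w * stats.norm.pdf(x, mu, sd)
             for w, mu, sd in zip(m0.weights, m0.means[:, 0], m0.stds[:, 0])]
            for x in X[:, 0]])
        R = joint / joint.sum(axis=1, keepdims=True)
        assert np.allclose(a.responsibilities, R, atol=1e-10)
        m1 = m_step(a, X)
        for k in range(2):
            w = R[:, k]
            mean = (w * X[:, 0]).sum() / w.sum()
            var = (w * (X[:, 0] - mean) ** 2).sum() / w.sum()
            assert abs(m1.weights[k] - w.mean()) < 1e-10
            assert abs(m1.means[k, 0] - mean) < 1e-10
            assert abs(m1.stds[k, 0] - np.sqrt(var)) < 1e-10

    def test_loglik_trace_monotone_on_random_data(self):
        """The likelihood rises every iteration until convergence."""
        rng = np.random.default_rng(9)
        for trial in range(10):
            K = int(rng.integers(1, 5))
            X = rng.normal(size=(60, 3)) + rng.integers(0, 3) * rng.normal(size=3)
            model, _ = fit_em(X, K, EMConfig(seed=trial))
            diffs = np.diff(model.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_weights_on_simplex_after_fit(self):
        rng = np.random.default_rng(12)
        model, a = fit_em(rng.normal(size=(50, 2)), 3, EMConfig(seed=12))
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(a.responsibilities.sum(axis=1), 1.0, atol=1e-12)

    def test_agrees_with_sklearn_density(self):
        """Same parameters, same log-likelihood as scikit-learn's mixture."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        model, _ = fit_em(X, 2, EMConfig(seed=7))
        gm = GaussianMixture(n_components=2, covariance_type="diag")
        gm.weights_ = model.weights
        gm.means_ = model.means
        gm.covariances_ = model.stds ** 2
        gm.precisions_cholesky_ = 1.0 / model.stds
        assert gm.score(X) * len(X) == pytest.approx(total_loglik(model, X),
                                                     abs=1e-6)


class TestSelectK:
    def test_single_blob_selects_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 2))
        best, curve = select_k_cv(X, EMConfig(seed=2, k_max=4))
        assert best == 1

    def test_three_blobs_selected(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(c, 0.5, 60) for c in (0, 10, 20)])[:, None]
        best, curve = select_k_cv(X, EMConfig(seed=0, k_max=6))
        assert best == 3
        assert len(curve) >= 4

    def test_k_max_one(self):
        rng = np.random.default_rng(1)
        best, curve = select_k_cv(rng.normal(size=(30, 1)),
                                  EMConfig(seed=1, k_max=1))
        assert best == 1 and len(curve) == 1

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            select_k_cv(np.zeros((5, 1)), EMConfig(cv_folds=10))


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 2))
    model, _ = fit_em(X, 2, EMConfig(seed=6))
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert back.K == model.K
    assert np.allclose(back.means, model.means)
    assert total_loglik(back, X) == pytest.approx(total_loglik(model, X))
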