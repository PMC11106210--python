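"""Training: design matrix, uncentered PCA, GMM, CoD, cluster elimination."""

from __future__ import annotations

import numpy as np
import pytest

from eodchirp.model_training import (
    GaussianCluster,
    TrainingError,
    assign_cluster,
    build_design_matrix,
    back_project_mean,
    coefficient_of_determination,
    eliminate_clusters,
    fit_gmm,
    fit_pca,
    posterior_log_scores,
    project,
    train_model,
)


class TestDesignMatrix:
    def test_shape_and_layout(self, g2_group):
        X = build_design_matrix(g2_group)
        assert X.shape == (len(g2_group), 2 * 101)
        # first half of a row is exactly that sample's phi
        np.testing.assert_array_equal(X[3, :101], g2_group.samples[3].phi)
        np.testing.assert_array_equal(X[3, 101:], g2_group.samples[3].a)

    def test_single_sample_matrix(self, g2_group):
        X = build_design_matrix(g2_group, [0])
        assert X.shape == (1, 202)

    def test_training_subset_selection(self, g2_group):
        X = build_design_matrix(g2_group, [2, 5, 7])
        assert X.shape[0] == 3
        np.testing.assert_array_equal(X[1, :101], g2_group.samples[5].phi)


class TestPCA:
    def test_two_point_hand_example(self):
        # X = [(1,0), (-1,0)]: X'X = diag(2, 0) -> PC1 = (1,0), eigenvalues (2,0)
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        basis = fit_pca(X)
        np.testing.assert_allclose(basis.eigenvalues, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(basis.components[:, 0]), [1.0, 0.0],
                                   atol=1e-12)
        assert basis.components[0, 0] > 0  # sign convention

    def test_orthonormality_and_reconstruction(self, g2_group):
        X = build_design_matrix(g2_group)
        basis = fit_pca(X)
        P = basis.components
        np.testing.assert_allclose(P.T @ P, np.eye(P.shape[1]), atol=1e-10)
        np.testing.assert_allclose(X @ P @ P.T, X, atol=1e-8)

    def test_explained_variance_monotone_to_one(self, g2_group):
        X = build_design_matrix(g2_group)
        basis = fit_pca(X)
        cum = np.cumsum(basis.explained_variance_ratio())
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0, abs=1e-12)

    def test_projection_preserves_norm_at_full_rank(self, g2_group):
        X = build_design_matrix(g2_group)
        basis = fit_pca(X)
        Y = project(X, basis, X.shape[1])
        assert np.linalg.norm(Y) == pytest.approx(np.linalg.norm(X), rel=1e-8)

    def test_projection_dimension_checks(self, g2_group):
        X = build_design_matrix(g2_group)
        basis = fit_pca(X)
        assert project(X, basis, 2).shape == (X.shape[0], 2)
        with pytest.raises(ValueError):
            project(X, basis, X.shape[1] + 1)


class TestGMM:
    def test_two_cluster_parameter_recovery(self, rng):
        pts = np.concatenate([
            rng.normal([5.0, 0.0], 0.3, (200, 2)),
            rng.normal([-5.0, 0.0], 0.3, (200, 2)),
        ])
        clusters = fit_gmm(pts, C=2, seed=0)
        means = sorted([tuple(c.mu) for c in clusters])
        assert np.allclose(means[0], (-5, 0), atol=0.1)
        assert np.allclose(means[1], (5, 0), atol=0.1)
        for c in clusters:
            assert c.p == pytest.approx(0.5, abs=0.05)

    def test_single_component_is_the_sample_mle(self, rng):
        pts = rng.normal(0, 1, (300, 3))
        (c,) = fit_gmm(pts, C=1, seed=0)
        np.testing.assert_allclose(c.mu, pts.mean(axis=0), atol=1e-6)
        cov = np.cov(pts.T, bias=True)
        np.testing.assert_allclose(c.Sigma, cov, atol=1e-4)
        assert c.p == 1.0

    def test_seeded_fit_is_deterministic(self, rng):
        pts = rng.normal(0, 1, (200, 2))
        a = fit_gmm(pts, C=3, seed=11)
        b = fit_gmm(pts, C=3, seed=11)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.mu, cb.mu)
            np.testing.assert_array_equal(ca.Sigma, cb.Sigma)

    def test_mixing_proportions_sum_to_one(self, rng):
        pts = rng.normal(0, 1, (200, 2))
        clusters = fit_gmm(pts, C=4, seed=3)
        assert sum(c.p for c in clusters) == pytest.approx(1.0, abs=1e-12)


def two_unit_clusters(p1=0.5):
    eye = np.eye(2)
    return [
        GaussianCluster(np.array([5.0, 0.0]), eye.copy(), p1),
        GaussianCluster(np.array([-5.0, 0.0]), eye.copy(), 1 - p1),
    ]


class TestAssignment:
    def test_cluster_center_assigns_to_itself(self):
        clusters = two_unit_clusters()
        assert assign_cluster(np.array([5.0, 0.0]), clusters) == 0
        assert assign_cluster(np.array([-5.0, 0.0]), clusters) == 1

    def test_equidistant_tie_goes_to_first(self):
        clusters = two_unit_clusters()
        assert assign_cluster(np.array([0.0, 0.0]), clusters) == 0

    def test_log_space_matches_direct_density_argmax(self, rng):
        # brute-force oracle: direct (unnormalized) posterior densities
        from scipy.stats import multivariate_normal

        clusters = [
            GaussianCluster(rng.normal(0, 3, 2),
                            np.diag(rng.uniform(0.5, 2, 2)),
                            p)
            for p in (0.2, 0.5, 0.3)
        ]
        for y in rng.normal(0, 3, (100, 2)):
            direct = np.array([
                c.p * multivariate_normal.pdf(y, c.mu, c.Sigma)
                for c in clusters
            ])
            assert assign_cluster(y, clusters) == int(np.argmax(direct))


class TestCoD:
    def test_perfect_match_is_one(self):
        f = np.array([0.0, 1.0, 2.0])
        assert coefficient_of_determination(f, f) == 1.0

    def test_reference_equal_to_mean_is_zero(self):
        f = np.array([0.0, 1.0, 2.0])
        ref = np.full(3, f.mean())
        assert coefficient_of_determination(f, ref) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        f = np.array([0.0, 1.0, 2.0, 3.0])
        ref = np.array([0.0, 1.0, 2.0, 5.0])
        assert coefficient_of_determination(f, ref) == pytest.approx(1 - 4 / 5)

    def test_constant_waveform_is_minus_infinity(self):
        f = np.full(5, 2.0)
        assert coefficient_of_determination(f, f) == float("-inf")


class TestElimination:
    def make(self, sizes, cods_per_cluster, props):
        clusters = [
            GaussianCluster(np.zeros(2), np.eye(2), p) for p in props
        ]
        assignments = np.concatenate(
            [np.full(n, c) for c, n in enumerate(sizes)]
        )
        cods = np.concatenate(
            [np.full(n, q) for n, q in zip(sizes, cods_per_cluster)]
        )
        return clusters, assignments, cods

    def test_good_large_cluster_kept(self):
        clusters, asg, cods = self.make([100], [0.9], [1.0])
        kept = eliminate_clusters(clusters, asg, cods)
        assert len(kept) == 1

    def test_small_cluster_eliminated_regardless_of_cod(self):
        clusters, asg, cods = self.make([20, 100], [0.99, 0.9], [0.2, 0.8])
        kept = eliminate_clusters(clusters, asg, cods)
        assert len(kept) == 1

    def test_low_cod_percentile_eliminates(self):
        clusters, asg, cods = self.make([100, 100], [0.1, 0.9], [0.5, 0.5])
        kept = eliminate_clusters(clusters, asg, cods)
        assert len(kept) == 1

    def test_renormalized_proportions(self):
        clusters, asg, cods = self.make(
            [100, 100, 20], [0.9, 0.9, 0.9], [0.5, 0.3, 0.2]
        )
        kept = eliminate_clusters(clusters, asg, cods)
        assert [c.p for c in kept] == pytest.approx([0.625, 0.375])
        assert sum(c.p for c in kept) == pytest.approx(1.0, abs=1e-12)

    def test_all_eliminated_is_an_error(self):
        clusters, asg, cods = self.make([10, 10], [0.9, 0.9], [0.5, 0.5])
        with pytest.raises(TrainingError):
            eliminate_clusters(clusters, asg, cods)


class TestTrainModel:
    def test_model_shapes_and_waveforms(self, trained_model):
        m = trained_model
        assert m.P_N.shape == (202, 2)
        assert 1 <= len(m.clusters) <= 2
        assert sum(c.p for c in m.clusters) == pytest.approx(1.0, abs=1e-12)
        for c in m.clusters:
            assert c.mean_f.shape == (101,)
            # back-projection consistency
            f_bar, a_bar = back_project_mean(c.mu, m.P_N, 101)
            np.testing.assert_array_equal(c.mean_f, f_bar)
            # type-2-like mean waveform: pronounced central rise
            assert c.mean_f[40:60].max() > 3 * np.abs(c.mean_f[:10]).max()

    def test_posteriors_finite_on_training_scores(self, g2_group, trained_model):
        X = build_design_matrix(g2_group)
        Y = X @ trained_model.P_N
        scores = posterior_log_scores(Y, trained_model.clusters)
        assert np.all(np.isfinite(scores))

    def test_subclustering_reuse_runs(self, g2_group, rng):
        # the sub-cluster analysis refits with more components in a deeper
        # projection (N=4, C=8) on member vectors; the fit itself must run
        X = build_design_matrix(g2_group)
        basis = fit_pca(X)
        Y = project(X, basis, 4)
        # too few real samples for C=8 identifiability; augment with jitter
        Yb = np.concatenate([Y + rng.normal(0, 0.01, Y.shape) for _ in range(5)])
        clusters = fit_gmm(Yb, C=8, seed=5)
        assert len(clusters) == 8
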