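"""Diffusion embedding validated against brute-force oracles at small n."""

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from arrestmap.manifold import (
    EmbeddingParams,
    build_kernel,
    diffusion_operator,
    embed,
    map_cells,
    potential_distances,
)
from arrestmap.simulate import PopulationSimConfig, simulate_population


def brute_force_kernel(X, knn, alpha=40.0):
    """O(n^2) double-loop recomputation of the alpha-decay kernel."""
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(np.sum((X[i] - X[j]) ** 2))
    sigma = np.array([np.sort(D[i])[knn] for i in range(n)])
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = 0.5 * (
                np.exp(-((D[i, j] / sigma[i]) ** alpha))
                + np.exp(-((D[i, j] / sigma[j]) ** alpha))
            )
    np.fill_diagonal(K, 1.0)
    return K


class TestKernel:
    def test_matches_brute_force_on_50_random_cells(self, rng):
        X = rng.normal(size=(50, 7))
        K = build_kernel(X, knn=5)
        np.testing.assert_allclose(K, brute_force_kernel(X, 5), atol=1e-6)

    def test_zero_distance_gives_unit_affinity(self, rng):
        X = rng.normal(size=(30, 4))
        X[7] = X[3]  # duplicate pair
        K = build_kernel(X, knn=3)
        assert K[3, 7] == pytest.approx(1.0)
        assert np.all(np.diag(K) == 1.0)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 5))
        perm = rng.permutation(40)
        K = build_kernel(X, knn=4)
        K_perm = build_kernel(X[perm], knn=4)
        np.testing.assert_allclose(K_perm, K[np.ix_(perm, perm)], atol=1e-12)

    def test_missing_values_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_kernel(X, knn=2)


class TestDiffusionOperator:
    def test_identity_kernel_gives_identity_operator(self):
        op = diffusion_operator(np.eye(8))
        np.testing.assert_allclose(op.P, np.eye(8))

    def test_rows_sum_to_one(self, rng):
        X = rng.normal(size=(60, 6))
        op = diffusion_operator(build_kernel(X, knn=5))
        np.testing.assert_allclose(op.P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(op.P >= 0)

    def test_p_squared_matches_brute_force(self, rng):
        X = rng.normal(size=(20, 4))
        op = diffusion_operator(build_kernel(X, knn=3))
        P2_brute = np.array(
            [[sum(op.P[i, k] * op.P[k, j] for k in range(20)) for j in range(20)]
             for i in range(20)]
        )
        np.testing.assert_allclose(op.P @ op.P, P2_brute, atol=1e-10)

    def test_isolated_cell_named_in_error(self):
        K = np.eye(5)
        K[2, 2] = 0.0
        with pytest.raises(ValueError, match="2"):
            diffusion_operator(K)

    def test_asymmetric_kernel_rejected(self):
        K = np.eye(4)
        K[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            diffusion_operator(K)


class TestPotentialDistances:
    def _chain_operator(self, n=10):
        """Nearest-neighbor chain graph kernel."""
        K = np.eye(n)
        for i in range(n - 1):
            K[i, i + 1] = K[i + 1, i] = 0.5
        return diffusion_operator(K)

    def test_identical_rows_give_zero_distance(self):
        K = np.ones((6, 6))
        op = diffusion_operator(K)
        D = potential_distances(op, t=3)
        np.testing.assert_allclose(D, 0.0, atol=1e-9)

    def test_symmetric_zero_diagonal(self, rng):
        X = rng.normal(size=(25, 5))
        op = diffusion_operator(build_kernel(X, knn=4))
        D = potential_distances(op, t=5)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_matches_brute_force_log_rows_on_chain(self):
        op = self._chain_operator(10)
        t, eps = 4, np.finfo(float).eps
        D = potential_distances(op, t=t, eps=eps)
        Pt = np.linalg.matrix_power(op.P, t)
        U = -np.log(Pt + eps)
        brute = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                brute[i, j] = np.sqrt(np.sum((U[i] - U[j]) ** 2))
        np.testing.assert_allclose(D, brute, atol=1e-6)

    def test_smoothing_in_t(self, rng):
        """Mean pairwise potential distance is non-increasing in t."""
        X = rng.normal(size=(100, 5))
        op = diffusion_operator(build_kernel(X, knn=8))
        means = [potential_distances(op, t=t).mean() for t in (1, 5, 20, 60)]
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_invalid_eps_rejected(self):
        op = self._chain_operator(5)
        with pytest.raises(ValueError, match="eps"):
            potential_distances(op, t=2, eps=0.0)


class TestEmbed:
    def test_three_equidistant_points_form_equilateral_triangle(self):
        D = np.full((3, 3), 1.0)
        np.fill_diagonal(D, 0.0)
        emb = embed(D)
        E = np.sqrt(((emb.coordinates[:, None] - emb.coordinates[None]) ** 2).sum(-1))
        sides = E[np.triu_indices(3, 1)]
        assert sides.max() / sides.min() < 1.01

    def test_duplicate_cell_lands_on_coincident_coordinates(self, rng):
        X = rng.normal(size=(20, 4))
        X[11] = X[4]
        op = diffusion_operator(build_kernel(X, knn=3))
        emb = embed(potential_distances(op, t=3))
        assert np.linalg.norm(emb.coordinates[11] - emb.coordinates[4]) < 1e-6

    def test_noiseless_curve_ordering_recovered(self, rng):
        """A 1-D curve embedded in 20-D unrolls with |Spearman| >= 0.95.

        Ordering is read off the principal axis of the embedded filament.
        """
        s = np.sort(rng.uniform(0, 1, 300))
        basis = rng.normal(size=(2, 20))
        X = np.outer(s, basis[0]) + 0.3 * np.outer(np.sin(1.5 * s), basis[1])
        emb = map_cells_from_matrix(X, knn=15, t=30)
        coords = emb.coordinates - emb.coordinates.mean(axis=0)
        axis = np.linalg.svd(coords, full_matrices=False)[2][0]
        rho = spearmanr(coords @ axis, s).statistic
        assert abs(rho) >= 0.95

    def test_nonfinite_distances_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = np.inf
        with pytest.raises(ValueError):
            embed(D)

    def test_permutation_invariance_up_to_rigid_motion(self, rng):
        X = rng.normal(size=(40, 5))
        perm = rng.permutation(40)
        op = diffusion_operator(build_kernel(X, knn=4))
        emb = embed(potential_distances(op, t=3))
        op_p = diffusion_operator(build_kernel(X[perm], knn=4))
        emb_p = embed(potential_distances(op_p, t=3))
        _, _, disparity = procrustes(emb.coordinates[perm], emb_p.coordinates)
        assert disparity < 1e-6


def map_cells_from_matrix(X, knn, t, gamma=1.0):
    """Helper: run the kernel->operator->distance->embed composition on a
    bare matrix."""
    op = diffusion_operator(build_kernel(X, knn=knn))
    return embed(potential_distances(op, t=t, gamma=gamma))


class TestMapCells:
    def test_two_separated_clusters_have_high_silhouette(self, rng):
        a = rng.normal(0, 1, size=(150, 8))
        b = rng.normal(6, 1, size=(150, 8))
        emb = map_cells_from_matrix(np.vstack([a, b]), knn=10, t=5)
        labels = np.array([0] * 150 + [1] * 150)
        assert silhouette_score(emb.coordinates, labels) > 0.5

    def test_same_seed_identical_coordinates(self, normalized_population):
        sub = normalized_population.subset(np.arange(400))
        params = EmbeddingParams(knn=20, t=10, seed=4)
        a = map_cells(sub, params)
        b = map_cells(sub, params)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_arrested_centroid_separates_from_cycling(
        self, small_population, normalized_population
    ):
        sub_idx = np.arange(800)
        emb = map_cells(
            normalized_population.subset(sub_idx), EmbeddingParams(knn=20, t=10)
        )
        states = small_population.data.loc[sub_idx, "arrest_state"].to_numpy()
        deep = small_population.data.loc[sub_idx, "latent_pseudotime"].to_numpy() > 0.5
        cyc = emb.coordinates[states == "cycling"]
        arr = emb.coordinates[(states != "cycling") & deep]
        sep = np.linalg.norm(cyc.mean(0) - arr.mean(0))
        spread = np.linalg.norm(cyc - cyc.mean(0), axis=1).mean()
        assert sep > spread
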