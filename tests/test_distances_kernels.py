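import numpy as np
import pytest

from codak import (
    CompositionMatrix,
    aitchison_distance,
    bray_curtis_distance,
    clr,
    closure,
    distance_induced_kernel,
    drop_component,
    euclidean_distance,
    gaussian_kernel,
    predictor_kernel,
    psd_clip,
    stratified_kernel,
    weighted_aitchison_distance,
)
from codak.distances import DistanceMatrix
from codak.kernels import KernelMatrix


def aitchison_double_sum(p_i, p_j):
    """Independent double-sum oracle: sqrt(1/(2q) sum_rs {ln(pr/ps) ratios}^2)."""
    q = len(p_i)
    total = 0.0
    for r in range(q):
        for s in range(q):
            total += (np.log(p_i[r] / p_i[s]) - np.log(p_j[r] / p_j[s])) ** 2
    return np.sqrt(total / (2 * q))


class TestAitchison:
    def test_frozen_example(self):
        P = CompositionMatrix([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25]])
        assert aitchison_distance(P).values[0, 1] == pytest.approx(np.sqrt(2) * np.log(2), abs=1e-10)

    def test_identical_rows_zero(self):
        P = CompositionMatrix([[0.2, 0.3, 0.5], [0.2, 0.3, 0.5]])
        assert aitchison_distance(P).values[0, 1] == 0.0

    def test_double_sum_form_agrees(self, random_composition):
        P = random_composition(n=5, q=6)
        D = aitchison_distance(P)
        for i in range(5):
            for j in range(i + 1, 5):
                assert D.values[i, j] == pytest.approx(
                    aitchison_double_sum(P.values[i], P.values[j]), abs=1e-8
                )

    def test_scale_invariance(self, rng):
        raw = rng.random((4, 5)) + 0.05
        scaled = raw.copy()
        scaled[1] *= 7.0
        D1 = aitchison_distance(CompositionMatrix(closure(raw)))
        D2 = aitchison_distance(CompositionMatrix(closure(scaled)))
        np.testing.assert_allclose(D1.values, D2.values, atol=1e-10)

    def test_metric_properties(self, random_composition):
        P = random_composition(n=9, q=6)
        D = aitchison_distance(P).values
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        for i in range(9):
            for j in range(9):
                for k in range(9):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-10

    def test_permutation_invariance(self, random_composition, rng):
        P = random_composition(n=6, q=7)
        perm = rng.permutation(7)
        Pp = CompositionMatrix(P.values[:, perm])
        np.testing.assert_allclose(
            aitchison_distance(P).values, aitchison_distance(Pp).values, atol=1e-10
        )

    def test_subcompositional_dominance(self, random_composition):
        P = random_composition(n=6, q=6)
        D = aitchison_distance(P).values
        for c in range(6):
            Dc = aitchison_distance(drop_component(P, c)).values
            assert np.all(Dc <= D + 1e-10)


class TestWeightedAitchison:
    def test_unit_weights_reduce_to_aitchison(self, random_composition):
        P = random_composition(n=7, q=5)
        Dw = weighted_aitchison_distance(P, np.ones(5))
        np.testing.assert_allclose(Dw.values, aitchison_distance(P).values, atol=1e-12)

    def test_doubling_weights_doubles_squared_distances(self, random_composition, rng):
        P = random_composition(n=5, q=6)
        w = rng.uniform(0.2, 3.0, size=6)
        D1 = weighted_aitchison_distance(P, w).values
        D2 = weighted_aitchison_distance(P, 2 * w).values
        np.testing.assert_allclose(D2**2, 2 * D1**2, atol=1e-10)

    def test_identical_rows_zero_any_weights(self, rng):
        row = closure(rng.random(5) + 0.1)
        P = CompositionMatrix(np.tile(row, (3, 1)))
        w = rng.uniform(0.1, 2.0, size=5)
        np.testing.assert_allclose(weighted_aitchison_distance(P, w).values, 0.0, atol=1e-12)

    def test_nonpositive_weight_rejected(self, random_composition):
        with pytest.raises(ValueError):
            weighted_aitchison_distance(random_composition(q=4), np.array([1.0, 0.0, 1.0, 1.0]))


class TestOtherDistances:
    def test_bray_curtis_example(self):
        M = np.array([[0.5, 0.5, 0.0], [0.25, 0.25, 0.5]])
        assert bray_curtis_distance(M).values[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_bray_curtis_bounds(self):
        disjoint = np.array([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.5, 0.5]])
        assert bray_curtis_distance(disjoint).values[0, 1] == pytest.approx(1.0)
        same = np.array([[0.2, 0.8], [0.2, 0.8]])
        assert bray_curtis_distance(same).values[0, 1] == pytest.approx(0.0)

    def test_euclidean_triangle(self):
        assert euclidean_distance(np.array([[0.0, 0.0], [3.0, 4.0]])).values[0, 1] == 5.0

    def test_euclidean_of_clr_is_aitchison(self, random_composition):
        P = random_composition(n=6, q=5)
        np.testing.assert_allclose(
            euclidean_distance(clr(P).values).values,
            aitchison_distance(P).values,
            atol=1e-10,
        )


class TestDistanceInducedKernel:
    def test_zero_distance_gives_zero_kernel(self):
        D = DistanceMatrix(np.zeros((4, 4)), "euclidean")
        np.testing.assert_allclose(distance_induced_kernel(D).values, 0.0, atol=1e-12)

    def test_gram_matrix_identity(self, rng):
        X = rng.normal(size=(8, 3))
        D = euclidean_distance(X)
        K = distance_induced_kernel(D).values
        H = np.eye(8) - np.ones((8, 8)) / 8
        np.testing.assert_allclose(K, H @ X @ X.T @ H, atol=1e-8)

    def test_row_sums_zero(self, rng):
        Y = rng.random((6, 4))
        K = distance_induced_kernel(euclidean_distance(Y)).values
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-8)

    def test_aitchison_kernel_is_psd(self, random_composition):
        K = distance_induced_kernel(aitchison_distance(random_composition(n=10, q=6)))
        assert np.linalg.eigvalsh(K.values).min() >= -1e-8


class TestGaussianKernel:
    def test_values(self):
        D = DistanceMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), "aitchison")
        K = gaussian_kernel(D, gamma=2.0)
        assert K.values[0, 0] == 1.0
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0))

    def test_median_bandwidth_and_monotonicity(self, random_composition):
        D = aitchison_distance(random_composition(n=8, q=5))
        K = gaussian_kernel(D, "median").values
        iu = np.triu_indices(8, 1)
        order = np.argsort(D.values[iu])
        assert np.all(np.diff(K[iu][order]) <= 1e-12)

    def test_degenerate_median_rejected(self):
        D = DistanceMatrix(np.zeros((3, 3)), "aitchison")
        with pytest.raises(ValueError, match="degenerate"):
            gaussian_kernel(D, "median")


class TestPredictorKernel:
    def test_binary_values(self):
        K = predictor_kernel(np.array(["ctrl", "case", "ctrl", "case"]), "binary").values
        assert K[0, 2] == pytest.approx(1.0)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_binary_psd(self, rng):
        x = rng.integers(0, 2, size=15)
        K = predictor_kernel(x, "binary").values
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_more_than_two_levels_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            predictor_kernel(np.array([0, 1, 2, 1]), "binary")

    def test_continuous_outer_product(self):
        K = predictor_kernel(np.array([1.0, -1.0]), "continuous").values
        np.testing.assert_allclose(K, [[1.0, -1.0], [-1.0, 1.0]], atol=1e-12)


class TestStratifiedKernel:
    def test_single_stratum_unchanged(self, random_composition):
        K = gaussian_kernel(aitchison_distance(random_composition(n=6, q=4)))
        Ks = stratified_kernel(K, np.zeros(6))
        np.testing.assert_allclose(Ks.values, K.values)

    def test_all_distinct_strata_gives_identity(self, random_composition):
        K = gaussian_kernel(aitchison_distance(random_composition(n=5, q=4)))
        with pytest.warns(UserWarning, match="single sample"):
            Ks = stratified_kernel(K, np.arange(5))
        np.testing.assert_allclose(Ks.values, np.eye(5), atol=1e-12)

    def test_positive_definite_on_random_instances(self, random_composition, rng):
        for trial in range(5):
            P = random_composition(n=12, q=5, seed=trial)
            strata = rng.integers(0, 3, size=12)
            K = stratified_kernel(gaussian_kernel(aitchison_distance(P)), strata)
            assert np.linalg.eigvalsh(K.values).min() > 0


class TestPsdClip:
    def test_already_psd_unchanged(self, random_composition):
        K = gaussian_kernel(aitchison_distance(random_composition(n=8, q=5)))
        clipped = psd_clip(K)
        assert not clipped.psd_clipped
        np.testing.assert_allclose(clipped.values, K.values, atol=1e-8)

    def test_indefinite_matrix_clipped(self):
        K = KernelMatrix(np.diag([1.0, -1.0]), "test")
        clipped = psd_clip(K)
        assert clipped.psd_clipped
        np.testing.assert_allclose(clipped.values, np.diag([1.0, 0.0]), atol=1e-12)

    def test_nearest_psd_among_spectral_truncations(self, rng):
        S = rng.normal(size=(6, 6))
        S = 0.5 * (S + S.T)
        clipped = psd_clip(KernelMatrix(S, "test")).values
        assert np.linalg.eigvalsh(clipped).min() >= -1e-8
        vals, vecs = np.linalg.eigh(S)
        best = np.linalg.norm(S - clipped)
        # zeroing any other subset of eigenvalues is no closer in Frobenius norm
        for _ in range(20):
            keep = rng.integers(0, 2, size=6).astype(bool)
            alt_vals = np.where(keep & (vals > 0), vals, 0.0)
            alt = (vecs * alt_vals) @ vecs.T
            assert best <= np.linalg.norm(S - alt) + 1e-10
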