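import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from archenet import (
    build_network,
    jsd_distance,
    kstar_neighbors,
    normalize_encodings,
    smooth_weights,
)
from archenet.network import jsd_to_many


def _random_distributions(rng, n, dim):
    P = rng.dirichlet(np.ones(dim) * 0.5, size=n)
    return P


class TestNormalize:
    def test_multi_level_blocks_divide_by_level_count(self, rng):
        blocks = [rng.dirichlet(np.ones(k), size=10).T for k in (2, 3, 4)]
        H = np.vstack(blocks)
        out = normalize_encodings(H)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(out, H / 3.0)

    def test_single_level_is_identity(self, rng):
        H = rng.dirichlet(np.ones(4), size=8).T
        assert np.allclose(normalize_encodings(H), H)

    def test_zero_column_rejected(self):
        H = np.zeros((3, 2))
        H[:, 0] = [0.2, 0.3, 0.5]
        with pytest.raises(ValueError):
            normalize_encodings(H)


class TestJSDMetric:
    def test_identity_and_disjoint_support(self):
        assert jsd_distance([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert jsd_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_scalar_evaluation_example(self):
        # direct base-2 evaluation of the divergence chain
        assert jsd_distance([0.5, 0.5], [1, 0]) == pytest.approx(0.55790, abs=5e-5)

    def test_matches_scipy_oracle(self, rng):
        P = _random_distributions(rng, 50, 6)
        for i in range(0, 50, 2):
            d_mine = jsd_distance(P[i], P[i + 1])
            d_scipy = jensenshannon(P[i], P[i + 1], base=2)
            assert d_mine == pytest.approx(float(d_scipy), abs=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        n = 10_000
        A = _random_distributions(rng, n, 5)
        B = _random_distributions(rng, n, 5)
        C = _random_distributions(rng, n, 5)
        for i in range(0, n, 500):  # symmetry exact, spot-checked in batches
            assert jsd_distance(A[i], B[i]) == jsd_distance(B[i], A[i])
        dAB = np.array([jsd_distance(a, b) for a, b in zip(A, B)])
        dBC = np.array([jsd_distance(b, c) for b, c in zip(B, C)])
        dAC = np.array([jsd_distance(a, c) for a, c in zip(A, C)])
        assert np.all(dAB >= 0) and np.all(dAB <= 1.0)
        assert np.all(dAC <= dAB + dBC + 1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            jsd_distance([0.5, 0.5], [1, 0, 0])
        with pytest.raises(ValueError):
            jsd_distance([-0.1, 1.1], [0.5, 0.5])


def _kstar_oracle(beta):
    """Literal line-by-line transcription of the selection pseudocode."""
    beta = list(beta)
    N = len(beta)
    if N == 1:
        return 1
    sum_b = 0.0
    sum_b2 = 0.0
    lam = beta[0] + 1.0
    for n in range(1, N):
        if lam <= beta[n - 1]:
            return n
        sum_b += beta[n - 1]
        sum_b2 += beta[n - 1] ** 2
        lam = (sum_b + (max(n + sum_b**2 - n * sum_b2, 0.0)) ** 0.5) / n
    return N - 1


class TestKStar:
    def test_one_near_rest_far_gives_small_count(self):
        beta = np.array([0.1, 5.0, 5.1, 5.2, 5.3, 5.4])
        assert kstar_neighbors(beta) == 2

    def test_equidistant_never_breaks_returns_all_but_one(self):
        for c in (0.5, 2.0, 7.0):
            beta = np.full(20, c)
            assert kstar_neighbors(beta) == 19

    def test_matches_literal_pseudocode_on_fuzzed_inputs(self, rng):
        for _ in range(1000):
            N = int(rng.integers(1, 40))
            beta = np.sort(rng.uniform(0, rng.uniform(0.5, 3.0), size=N))
            assert kstar_neighbors(beta) == _kstar_oracle(beta)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kstar_neighbors(np.array([]))


class TestSmoothWeights:
    def test_analytic_three_tied_neighbors(self):
        # 1 + 3 exp(-d/sigma) = log2(4) = 2  =>  sigma = d / ln 3
        d = 0.3
        w = smooth_weights(np.array([0.2, 0.2 + d, 0.2 + d, 0.2 + d]))
        assert w[0] == pytest.approx(1.0)
        assert np.allclose(w[1:], 1.0 / 3.0, atol=1e-5)
        assert w.sum() == pytest.approx(2.0, abs=1e-5)

    def test_normalization_constraint_on_random_rows(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 30))
            d = np.sort(rng.uniform(0, 1, size=k))
            if d[-1] == d[0]:
                continue
            w = smooth_weights(d)
            assert w.sum() == pytest.approx(np.log2(k), abs=1e-5)
            # k = 2 saturates only as sigma -> 0, where the far weight
            # underflows to exactly zero; all others stay strictly positive
            assert np.all(w >= 0) and np.all(w <= 1.0 + 1e-12)
            assert w[0] == pytest.approx(1.0)

    def test_single_neighbor_weight_one(self):
        assert smooth_weights(np.array([0.7])) == pytest.approx([1.0])

    def test_non_ascending_rejected(self):
        with pytest.raises(ValueError):
            smooth_weights(np.array([0.5, 0.2]))


class TestBuildNetwork:
    def _grouped_encodings(self, rng, groups=3, per=40, noise=0.15):
        H = np.zeros((groups, groups * per))
        for g in range(groups):
            H[g, g * per : (g + 1) * per] = 1.0
        H = H + rng.uniform(0, noise, H.shape)
        return H / H.sum(axis=0)

    def test_planted_groups_give_modular_graph(self, rng):
        H = self._grouped_encodings(rng)
        net = build_network(H)
        labels = np.repeat(np.arange(3), 40).tolist()
        assert net.igraph().modularity(labels, weights="weight") > 0.5

    def test_kappa_increase_never_adds_edges(self, rng):
        H = self._grouped_encodings(rng)
        e1 = build_network(H, kappa=1.0).n_edges
        e2 = build_network(H, kappa=2.0).n_edges
        assert e2 <= e1

    def test_weights_symmetric_bounded_no_selfloops(self, rng):
        H = self._grouped_encodings(rng)
        net = build_network(H)
        W = net.weights
        assert (W != W.T).nnz == 0
        assert W.diagonal().sum() == 0
        assert np.all(W.data > 0) and np.all(W.data <= 1.0 + 1e-12)
        assert np.all(net.neighbor_counts >= 1)

    def test_approximate_backend_agrees_with_brute_force(self, rng):
        P = rng.dirichlet(np.ones(8) * 0.4, size=500).T
        approx = build_network(P)
        exact = build_network(P, exact=True)
        ea = set(zip(*approx.weights.nonzero()))
        ee = set(zip(*exact.weights.nonzero()))
        overlap = len(ea & ee) / len(ee)
        assert overlap >= 0.9

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            build_network(np.array([[1.0]]))
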