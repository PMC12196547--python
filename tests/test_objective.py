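"""MMD, weighted cross-entropy and the composite loss."""

import numpy as np
import pytest

from gaitpd import (
    LossWeights,
    kernel_bandwidth,
    mmd_layer_loss,
    mmd_squared,
    total_loss,
    weighted_cross_entropy,
)
from gaitpd.autodiff import Tensor


def brute_mmd(X, Y, gamma):
    """O(n^2) double-loop unbiased estimator (independent oracle)."""
    n, m = len(X), len(Y)
    k = lambda a, b: np.exp(-gamma * np.sum((a - b) ** 2))
    sx = sum(k(X[i], X[j]) for i in range(n) for j in range(n) if i != j)
    sy = sum(k(Y[i], Y[j]) for i in range(m) for j in range(m) if i != j)
    sxy = sum(k(X[i], Y[j]) for i in range(n) for j in range(m))
    return sx / (n * (n - 1)) + sy / (m * (m - 1)) - 2 * sxy / (n * m)


class TestKernelBandwidth:
    def test_single_pair_distance_two(self):
        X = np.array([[0.0, 0.0]])
        Y = np.array([[2.0, 0.0]])
        assert kernel_bandwidth(X, Y) == pytest.approx(0.25)

    def test_scaling_homogeneity(self, rng):
        X, Y = rng.normal(size=(6, 3)), rng.normal(size=(5, 3))
        g1 = kernel_bandwidth(X, Y)
        g2 = kernel_bandwidth(3 * X, 3 * Y)
        assert g2 == pytest.approx(g1 / 9.0, rel=1e-9)

    def test_matches_explicit_median_oracle(self, rng):
        X, Y = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        Z = np.vstack([X, Y])
        dists = [np.linalg.norm(Z[i] - Z[j])
                 for i in range(len(Z)) for j in range(i + 1, len(Z))]
        assert kernel_bandwidth(X, Y) == pytest.approx(1.0 / np.median(dists) ** 2)

    def test_identical_points_fall_back_to_one(self):
        X = np.ones((3, 2))
        with pytest.warns(UserWarning, match="identical"):
            assert kernel_bandwidth(X, X) == 1.0


class TestMMDSquared:
    def test_identical_duplicated_points_give_zero(self):
        p = np.array([[1.0, 2.0]])
        X = np.vstack([p, p])
        assert mmd_squared(X, X.copy(), gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_far_separated_tight_clusters_approach_two(self, rng):
        X = rng.normal(0, 1e-4, size=(8, 3))
        Y = rng.normal(0, 1e-4, size=(8, 3)) + 1e4
        assert mmd_squared(X, Y, gamma=1.0) == pytest.approx(2.0, abs=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        for n, m in [(8, 8), (5, 9), (32, 16)]:
            X, Y = rng.normal(size=(n, 4)), rng.normal(size=(m, 4)) + 0.3
            gamma = kernel_bandwidth(X, Y)
            assert mmd_squared(X, Y, gamma) == pytest.approx(
                brute_mmd(X, Y, gamma), abs=1e-10
            )

    def test_symmetry_and_permutation_invariance(self, rng):
        X, Y = rng.normal(size=(7, 3)), rng.normal(size=(6, 3))
        g = 0.7
        assert mmd_squared(X, Y, g) == pytest.approx(mmd_squared(Y, X, g), abs=1e-12)
        perm = rng.permutation(7)
        assert mmd_squared(X[perm], Y, g) == pytest.approx(
            mmd_squared(X, Y, g), abs=1e-12
        )

    def test_rejects_tiny_sets(self):
        with pytest.raises(ValueError, match="2 points"):
            mmd_squared(np.zeros((1, 2)), np.zeros((4, 2)), 1.0)


class TestLayerLoss:
    def test_identical_features_give_zero(self, rng):
        feats = [rng.normal(size=(6, 10, 4)) for _ in range(4)]
        L_d, per = mmd_layer_loss(feats, [f.copy() for f in feats])
        assert float(L_d.data) == pytest.approx(0.0, abs=1e-9)
        assert per == pytest.approx([0.0] * 4, abs=1e-9)

    def test_single_layer_mean_is_that_layer(self, rng):
        F = [rng.normal(size=(6, 8))]
        L = [rng.normal(size=(6, 8)) + 2.0]
        L_d, per = mmd_layer_loss(F, L)
        assert float(L_d.data) == pytest.approx(per[0])

    def test_mean_of_four_layers(self, rng):
        # construct layers with known discrepancies by reusing single-layer values
        F = [rng.normal(size=(8, 5)) for _ in range(4)]
        L = [f.copy() for f in F[:2]] + [rng.normal(size=(8, 5)) + 1.5 for _ in range(2)]
        L_d, per = mmd_layer_loss(F, L)
        assert float(L_d.data) == pytest.approx(np.mean(per), abs=1e-9)
        assert per[0] == pytest.approx(0.0, abs=1e-9)
        assert all(p >= 0 for p in per)

    def test_batch_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mmd_layer_loss([np.zeros((1, 3))], [np.zeros((1, 3))])

    def test_gradient_nonzero_when_distributions_differ(self, rng):
        F = Tensor(rng.normal(size=(6, 8)), requires_grad=True)
        L = Tensor(rng.normal(size=(6, 8)) + 1.0, requires_grad=True)
        L_d, _ = mmd_layer_loss([F], [L], max_points=None)
        L_d.backward()
        assert np.abs(F.grad).max() > 0


class TestMMDProperties:
    """Property-based invariants of the discrepancy estimator."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 2**31 - 1), gamma=st.floats(0.01, 10.0),
           n=st.integers(2, 12), m=st.integers(2, 12))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_symmetry_for_random_sets(self, seed, gamma, n, m):
        r = np.random.default_rng(seed)
        X, Y = r.normal(size=(n, 3)), r.normal(size=(m, 3))
        assert mmd_squared(X, Y, gamma) == pytest.approx(
            mmd_squared(Y, X, gamma), abs=1e-12
        )

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_bounded_by_kernel_range(self, seed):
        r = np.random.default_rng(seed)
        X, Y = r.normal(size=(6, 4)), r.normal(size=(6, 4)) + 3.0
        v = mmd_squared(X, Y, kernel_bandwidth(X, Y))
        assert -2.0 <= v <= 2.0  # Gaussian kernel in (0, 1]


class TestWeightedCrossEntropy:
    def test_perfect_confident_predictions_near_zero(self):
        probs = np.array([[0.0001, 0.9999], [0.9999, 0.0001]])
        labels = np.array([1, 0])
        assert float(weighted_cross_entropy(probs, labels).data) < 1e-3

    def test_equal_weights_reduce_to_standard_ce(self, rng):
        p = rng.uniform(0.05, 0.95, size=8)
        probs = np.stack([1 - p, p], axis=1)
        labels = rng.integers(0, 2, 8)
        got = float(weighted_cross_entropy(probs, labels, 1.0, 1.0).data)
        expected = -np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_single_sample_hand_value(self):
        probs = np.array([[0.5, 0.5]])
        got = float(weighted_cross_entropy(probs, np.array([1]), w1=0.9, w2=1.1).data)
        assert got == pytest.approx(0.9 * (-np.log(0.5)), rel=1e-9)  # ~0.6238

    def test_extreme_probabilities_clamped(self):
        probs = np.array([[1.0, 0.0]])
        val = float(weighted_cross_entropy(probs, np.array([1])).data)
        assert np.isfinite(val)


class TestTotalLoss:
    def _setup(self, rng):
        p = rng.uniform(0.1, 0.9, size=6)
        probs = Tensor(np.stack([1 - p, p], axis=1))
        labels = rng.integers(0, 2, 6)
        F = [Tensor(rng.normal(size=(6, 5)).astype(np.float64)) for _ in range(2)]
        L = [Tensor(rng.normal(size=(6, 5)) + 0.5) for _ in range(2)]
        W = [Tensor(rng.normal(size=(3, 3)), requires_grad=True)]
        return probs, labels, F, L, W

    def test_zero_lambdas_leave_only_ce(self, rng):
        probs, labels, F, L, W = self._setup(rng)
        w = LossWeights(lambda1=0.0, lambda2=0.0, lambda3=0.0)
        bd = total_loss(probs, labels, F, L, w, W)
        assert bd.total_value == pytest.approx(bd.L_w, rel=1e-9)

    def test_breakdown_identity(self, rng):
        probs, labels, F, L, W = self._setup(rng)
        w = LossWeights()
        bd = total_loss(probs, labels, F, L, w, W, rng=rng)
        assert bd.total_value == pytest.approx(
            bd.L_w + w.lambda1 * bd.L_d + w.lambda2 * bd.l1 + w.lambda3 * bd.l2,
            rel=1e-6,
        )
        assert bd.L_d == pytest.approx(np.mean(bd.per_layer_D), rel=1e-6)

    def test_zero_weights_zero_regularizers(self, rng):
        probs, labels, F, L, _ = self._setup(rng)
        W = [Tensor(np.zeros((4, 4)), requires_grad=True)]
        bd = total_loss(probs, labels, F, L, LossWeights(), W, rng=rng)
        assert bd.l1 == 0.0 and bd.l2 == 0.0

    def test_monotone_in_each_lambda(self, rng):
        probs, labels, F, L, W = self._setup(rng)
        base = total_loss(probs, labels, F, L, LossWeights(), W,
                          rng=np.random.default_rng(0)).total_value
        for kw in ({"lambda1": 0.1}, {"lambda2": 0.01}, {"lambda3": 0.01}):
            more = total_loss(probs, labels, F, L, LossWeights(**kw), W,
                              rng=np.random.default_rng(0)).total_value
            assert more >= base - 1e-12
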