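"""State-space routes, attention blocks and the dual-stream network."""

import numpy as np
import pytest

from gaitpd import (
    CMSANet,
    ModelConfig,
    SSMParams,
    cmsa_forward,
    load_checkpoint,
    save_checkpoint,
    ssd_forward,
    ssm_materialize,
    ssm_scan,
)
from gaitpd.autodiff import Tensor
from gaitpd.nn import MultiheadAttention
from gaitpd.network import Mamba2Block, SelfAttentionBlock


def random_ssm(rng, T, H=3, P=4, N=32):
    x = rng.normal(size=(T, H, P))
    a = rng.uniform(0.05, 0.999, size=(T, H))
    B = rng.normal(size=(T, N))
    C = rng.normal(size=(T, N))
    return x, SSMParams(a, B, C)


def apply_M(M, x):
    return np.einsum("hji,ihp->jhp", M, x)


class TestSSMRoutes:
    def test_memoryless_when_decay_zero(self):
        rng = np.random.default_rng(0)
        x, p = random_ssm(rng, 12)
        p0 = SSMParams(np.zeros_like(p.a), p.B, p.C)
        y = ssm_scan(x, p0)
        expected = np.einsum("tn,tn->t", p0.C, p0.B)[:, None, None] * x
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_scalar_identity_params_give_cumulative_sum(self):
        T = 10
        x = np.arange(T, dtype=float).reshape(T, 1, 1)
        p = SSMParams(np.ones((T, 1)), np.ones((T, 1)), np.ones((T, 1)))
        y = ssm_scan(x, p)
        np.testing.assert_allclose(y[:, 0, 0], np.cumsum(np.arange(T)), atol=1e-12)

    def test_materialize_length_one_and_diagonal(self):
        rng = np.random.default_rng(1)
        x, p = random_ssm(rng, 1)
        M = ssm_materialize(p)
        assert M.shape == (3, 1, 1)
        np.testing.assert_allclose(M[:, 0, 0], float(p.C[0] @ p.B[0]), atol=1e-12)
        # all-zero decay -> strictly diagonal M
        x, p = random_ssm(rng, 8)
        Md = ssm_materialize(SSMParams(np.zeros_like(p.a), p.B, p.C))
        off = Md.copy()
        for h in range(3):
            np.fill_diagonal(off[h], 0.0)
        assert np.abs(off).max() == 0.0

    def test_materialize_is_lower_triangular(self):
        rng = np.random.default_rng(2)
        x, p = random_ssm(rng, 16)
        M = ssm_materialize(p)
        for h in range(M.shape[0]):
            assert np.abs(np.triu(M[h], k=1)).max() == 0.0

    def test_materialize_guard(self):
        rng = np.random.default_rng(3)
        x, p = random_ssm(rng, 300)
        with pytest.raises(ValueError, match="guard"):
            ssm_materialize(p)

    def test_three_routes_agree_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            T = int(rng.integers(2, 65))
            x, p = random_ssm(rng, T)
            y_scan = ssm_scan(x, p)
            y_mat = apply_M(ssm_materialize(p), x)
            y_ssd = ssd_forward(x, p, chunk_size=10)
            np.testing.assert_allclose(y_mat, y_scan, atol=1e-5)
            np.testing.assert_allclose(y_ssd, y_scan, atol=1e-5)

    @pytest.mark.parametrize("chunk", [1, 50, 64])
    def test_degenerate_chunkings_match_scan(self, chunk):
        rng = np.random.default_rng(5)
        x, p = random_ssm(rng, 50)
        np.testing.assert_allclose(
            ssd_forward(x, p, chunk_size=chunk), ssm_scan(x, p), atol=1e-10
        )

    def test_ssd_rejects_nonpositive_decay(self):
        rng = np.random.default_rng(6)
        x, p = random_ssm(rng, 10)
        bad = SSMParams(np.zeros_like(p.a), p.B, p.C)
        with pytest.raises(ValueError, match="positive"):
            ssd_forward(x, bad, chunk_size=5)


class TestAttention:
    def test_single_token_softmax_is_identity_weight(self):
        rng = np.random.default_rng(0)
        mha = MultiheadAttention(6, 1, rng)
        x = Tensor(rng.normal(size=(1, 1, 6)).astype(np.float32))
        out = mha(x, x)
        v = x.data @ mha.wv.W.data + mha.wv.b.data
        expected = v @ mha.wo.W.data + mha.wo.b.data
        np.testing.assert_allclose(out.data, expected, atol=1e-5)

    def test_two_token_single_head_hand_computed(self):
        """Matches softmax(Q K^T / sqrt(d_k)) V computed by hand."""
        rng = np.random.default_rng(1)
        d = 4
        mha = MultiheadAttention(d, 1, rng)
        x = rng.normal(size=(1, 2, d)).astype(np.float32)
        out = mha(Tensor(x), Tensor(x)).data

        q = x[0] @ mha.wq.W.data + mha.wq.b.data
        k = x[0] @ mha.wk.W.data + mha.wk.b.data
        v = x[0] @ mha.wv.W.data + mha.wv.b.data
        scores = q @ k.T / np.sqrt(d)
        w = np.exp(scores - scores.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        expected = (w @ v) @ mha.wo.W.data + mha.wo.b.data
        np.testing.assert_allclose(out[0], expected, atol=1e-5)

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        mha = MultiheadAttention(39, 3, rng)
        x = Tensor(rng.normal(size=(2, 7, 39)).astype(np.float32))
        q = mha._split(mha.wq(x), 2, 7)
        k = mha._split(mha.wk(x), 2, 7)
        attn = ((q @ k.swapaxes(-1, -2)) * (1 / np.sqrt(13))).softmax(-1)
        np.testing.assert_allclose(attn.data.sum(-1), 1.0, atol=1e-5)

    def test_dim_not_divisible_by_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiheadAttention(10, 3, np.random.default_rng(0))


class TestMamba2Block:
    def test_output_shape_matches_input(self):
        cfg = ModelConfig()
        blk = Mamba2Block(cfg, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(2, 50, 39)).astype(np.float32))
        assert blk(x).shape == x.shape

    def test_chunking_internally_consistent(self):
        rng = np.random.default_rng(2)
        blk_small = Mamba2Block(ModelConfig(chunk_size=10), rng)
        blk_full = Mamba2Block(ModelConfig(chunk_size=50), np.random.default_rng(2))
        x = Tensor(np.random.default_rng(3).normal(size=(2, 50, 39)).astype(np.float32))
        np.testing.assert_allclose(
            blk_small(x).data, blk_full(x).data, atol=1e-4
        )


@pytest.fixture(scope="module")
def model():
    return CMSANet(ModelConfig(), seed=0)


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(7)
    return (rng.normal(size=(4, 50, 39)).astype(np.float32),
            rng.normal(size=(4, 50, 39)).astype(np.float32))


class TestCMSANet:
    def test_probabilities_normalized(self, model, batch):
        probs, _, _ = cmsa_forward(*batch, model)
        assert probs.shape == (4, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_per_layer_features_match_depth(self, model, batch):
        _, ff, fl = cmsa_forward(*batch, model)
        assert len(ff) == len(fl) == 4

    def test_batch_equivariance_under_sample_swap(self, model, batch):
        xf, xl = batch
        probs, _, _ = cmsa_forward(xf, xl, model)
        perm = [1, 0, 3, 2]
        probs_p, _, _ = cmsa_forward(xf[perm], xl[perm], model)
        np.testing.assert_allclose(probs_p, probs[perm], atol=1e-5)

    def test_inference_is_deterministic_without_dropout(self, model, batch):
        p1, _, _ = cmsa_forward(*batch, model)
        p2, _, _ = cmsa_forward(*batch, model)
        np.testing.assert_array_equal(p1, p2)

    def test_wrong_feature_width_rejected(self, model):
        bad = np.zeros((2, 50, 17), dtype=np.float32)
        with pytest.raises(ValueError, match="features"):
            model.forward(bad, bad)

    def test_gradient_reaches_both_streams(self, model, batch):
        from gaitpd import LossWeights, total_loss

        probs, ff, fl = model.forward(*batch)
        bd = total_loss(probs, np.array([0, 1, 0, 1]), ff, fl, LossWeights(),
                        model.weight_matrices(), rng=np.random.default_rng(0))
        for p in model.parameters():
            p.grad = None
        bd.total.backward()
        f_norm = sum(float(np.abs(p.grad).sum())
                     for blk in model.blocks_f for p in blk.parameters())
        l_norm = sum(float(np.abs(p.grad).sum())
                     for blk in model.blocks_l for p in blk.parameters())
        assert f_norm > 0 and l_norm > 0

    def test_depth_must_be_even(self):
        with pytest.raises(ValueError, match="even"):
            ModelConfig(depth=3)

    def test_checkpoint_round_trip(self, model, batch, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(path, model, preprocessing={"mu": [0.0]})
        loaded, pre = load_checkpoint(path)
        assert pre == {"mu": [0.0]}
        p1, _, _ = cmsa_forward(*batch, model)
        p2, _, _ = cmsa_forward(*batch, loaded)
        np.testing.assert_array_equal(p1, p2)
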