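"""CMSA-Net: dual-stream gait fusion network.

Two weight-independent streams (frontal and lateral view) of alternating
self-attention and Mamba-2 blocks, with a bidirectional cross-attention
exchange after every layer, temporal mean pooling, and a linear + softmax
classifier on the concatenated stream features.

The Mamba-2 block is built on a scalar-per-head state-space model: with
per-timestep decay ``a_t`` (scalar per head times the identity), input map
``B_t`` and output map ``C_t`` of state dimension N,

    h_t = a_t h_{t-1} + B_t x_t,      y_t = C_t^T h_t .

Unrolling the recursion shows the map x -> y is multiplication by a
lower-triangular semiseparable matrix ``M`` with
``M[j, i] = C_j^T (prod_{k=i+1..j} a_k) B_i``. Three equivalent routes are
implemented: the literal recursion (:func:`ssm_scan`), dense
materialization of ``M`` (:func:`ssm_materialize`, the O(T^2) oracle), and
the chunked semiseparable algorithm (:func:`ssd_forward`) used inside the
network, which processes the sequence in blocks of ``chunk_size`` frames
with dense within-chunk products and low-rank state passing across chunks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, stack
from .nn import DTYPE, Dropout, FeedForward, LayerNorm, Linear, Module, MultiheadAttention

__all__ = [
    "ModelConfig", "SSMParams",
    "ssm_scan", "ssm_materialize", "ssd_forward",
    "SelfAttentionBlock", "Mamba2Block", "CrossAttentionExchange", "CMSANet",
    "cmsa_forward", "save_checkpoint", "load_checkpoint",
]

_MATERIALIZE_GUARD = 256


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the tuned experiment)."""

    seq_len: int = 50
    embed_dim: int = 39
    heads: int = 3
    ffn_dim: int = 64
    dropout: float = 0.2
    depth: int = 4
    ssm_state_dim: int = 32
    conv_kernel: int = 1
    expansion: int = 1
    chunk_size: int = 10

    def __post_init__(self):
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.depth % 2:
            raise ValueError("depth must be even (alternating block types)")
        if self.conv_kernel != 1:
            raise ValueError("only kernel-size-1 depthwise convolution is supported")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


@dataclass
class SSMParams:
    """Per-timestep state-space quantities.

    ``a``: (..., T, H) scalar-per-head decays; ``B``, ``C``: (..., T, N)
    input/output maps shared across heads.
    """

    a: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.a.shape[-2] != self.B.shape[-2] or self.B.shape[-2] != self.C.shape[-2]:
            raise ValueError("a, B, C must agree on sequence length")
        if self.B.shape[-1] != self.C.shape[-1]:
            raise ValueError("B and C must share the state dimension")

    @property
    def length(self) -> int:
        return self.a.shape[-2]


# ----------------------------------------------------------- SSM routes

def ssm_scan(x: np.ndarray, params: SSMParams) -> np.ndarray:
    """Literal recursion h_t = a_t h_{t-1} + B_t x_t, y_t = C_t^T h_t.

    ``x`` is (T, H, P) or (b, T, H, P); the state starts at zero.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    a = params.a if params.a.ndim == 3 else params.a[None]
    B = params.B if params.B.ndim == 3 else params.B[None]
    C = params.C if params.C.ndim == 3 else params.C[None]
    b, T, H, P = x.shape
    N = B.shape[-1]
    h = np.zeros((b, H, N, P))
    y = np.empty_like(x)
    for t in range(T):
        h = a[:, t, :, None, None] * h + B[:, t, None, :, None] * x[:, t, :, None, :]
        y[:, t] = np.einsum("bn,bhnp->bhp", C[:, t], h)
    return y[0] if squeeze else y


def ssm_materialize(params: SSMParams, length: int | None = None) -> np.ndarray:
    """Dense lower-triangular transfer matrix M with
    ``M[..., h, j, i] = C_j . B_i * prod_{k=i+1..j} a_k`` (empty product = 1).

    This is the O(T^2) oracle route; lengths above 256 are refused.
    """
    a = params.a if params.a.ndim == 3 else params.a[None]
    B = params.B if params.B.ndim == 3 else params.B[None]
    C = params.C if params.C.ndim == 3 else params.C[None]
    squeeze = params.a.ndim == 2
    T = a.shape[1]
    if length is not None and length != T:
        raise ValueError("length must match the parameter sequence length")
    if T > _MATERIALIZE_GUARD:
        raise ValueError(
            f"materialization guard: length {T} > {_MATERIALIZE_GUARD} (oracle-only routine)"
        )
    b, _, H = a.shape
    G = np.einsum("bjn,bin->bji", C, B)  # C_j . B_i, shared across heads
    M = np.zeros((b, H, T, T))
    for j in range(T):
        M[:, :, j, j] = G[:, j, j, None]
        if j > 0:
            # decay[i] = prod_{k=i+1..j} a_k, built by reverse accumulation
            decay = np.multiply.accumulate(a[:, j:0:-1, :], axis=1)  # (b, j, H)
            decay = decay[:, ::-1, :]
            M[:, :, j, :j] = (G[:, j, :j, None] * decay).transpose(0, 2, 1)
    return M[0] if squeeze else M


def _ssd_tensor(x: Tensor, a: Tensor, B: Tensor, C: Tensor, Q: int) -> Tensor:
    """Chunked semiseparable computation on autodiff tensors.

    Shapes: x (b, T, H, P), a (b, T, H) with a > 0, B/C (b, T, N).
    Equals the scan to float tolerance for any chunk size.
    """
    b, T, H, P = x.shape
    N = B.shape[-1]
    pad = (-T) % Q
    if pad:
        x = concat([x, Tensor(np.zeros((b, pad, H, P), dtype=x.dtype))], axis=1)
        a = concat([a, Tensor(np.ones((b, pad, H), dtype=a.dtype))], axis=1)
        B = concat([B, Tensor(np.zeros((b, pad, N), dtype=B.dtype))], axis=1)
        C = concat([C, Tensor(np.zeros((b, pad, N), dtype=C.dtype))], axis=1)
    Tp = T + pad
    nc = Tp // Q
    xr = x.reshape(b, nc, Q, H, P)
    ar = a.reshape(b, nc, Q, H)
    Br = B.reshape(b, nc, Q, N)
    Cr = C.reshape(b, nc, Q, N)

    cum = ar.log().cumsum(axis=2)  # (b, nc, Q, H)
    tril = np.tril(np.ones((Q, Q), dtype=x.dtype)).reshape(1, 1, Q, Q, 1)
    diff = cum.reshape(b, nc, Q, 1, H) - cum.reshape(b, nc, 1, Q, H)
    # zero masked entries *before* exp so the upper triangle cannot overflow
    L = (diff * tril).exp() * tril  # (b, nc, Q, Q, H)

    G = Cr @ Br.swapaxes(-1, -2)  # (b, nc, Q, Q)
    Mc = G.reshape(b, nc, Q, Q, 1) * L
    y_intra = (
        Mc.transpose(0, 1, 4, 2, 3) @ xr.transpose(0, 1, 3, 2, 4)
    ).transpose(0, 1, 3, 2, 4)  # (b, nc, Q, H, P)

    cum_last = cum[:, :, Q - 1 : Q, :]  # (b, nc, 1, H)
    decay_to_end = (cum_last - cum).exp()  # (b, nc, Q, H)
    wx = (xr * decay_to_end.reshape(b, nc, Q, H, 1)).reshape(b, nc, Q, H * P)
    S = Br.swapaxes(-1, -2) @ wx  # (b, nc, N, H*P)

    R = Tensor(np.zeros((b, N, H * P), dtype=x.dtype))
    inter = []
    for c in range(nc):
        Cc = Cr[:, c]  # (b, Q, N)
        y_c = (Cc @ R).reshape(b, Q, H, P) * cum[:, c].exp().reshape(b, Q, H, 1)
        inter.append(y_c)
        # per-head decay over the whole chunk, applied to the running state
        dec = cum_last[:, c].exp().reshape(b, 1, H, 1)
        R = (R.reshape(b, N, H, P) * dec).reshape(b, N, H * P) + S[:, c]
    y_inter = stack(inter, axis=1)  # (b, nc, Q, H, P)
    y = (y_intra + y_inter).reshape(b, Tp, H, P)
    if pad:
        y = y[:, :T]
    return y


def ssd_forward(
    x: np.ndarray | Tensor,
    params: SSMParams | None = None,
    chunk_size: int = 10,
    *,
    a: Tensor | None = None,
    B: Tensor | None = None,
    C: Tensor | None = None,
) -> np.ndarray | Tensor:
    """Chunked SSD route; equals :func:`ssm_scan` to float tolerance.

    Accepts either an :class:`SSMParams` (NumPy convenience, requires all
    decays > 0) or explicit tensors (internal differentiable path).
    """
    if params is not None:
        xv = np.asarray(x, dtype=float)
        squeeze = xv.ndim == 3
        if squeeze:
            xv = xv[None]
        av = params.a if params.a.ndim == 3 else params.a[None]
        if np.any(av <= 0):
            raise ValueError("ssd_forward requires strictly positive decays a_t")
        Bv = params.B if params.B.ndim == 3 else params.B[None]
        Cv = params.C if params.C.ndim == 3 else params.C[None]
        y = _ssd_tensor(Tensor(xv), Tensor(av), Tensor(Bv), Tensor(Cv), chunk_size)
        return y.data[0] if squeeze else y.data
    return _ssd_tensor(x, a, B, C, chunk_size)


# ------------------------------------------------------------- blocks

class SelfAttentionBlock(Module):
    """Post-norm transformer block: multi-head self-attention + FFN."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.attn = MultiheadAttention(cfg.embed_dim, cfg.heads, rng)
        self.ffn = FeedForward(cfg.embed_dim, cfg.ffn_dim, rng)
        self.ln1 = LayerNorm(cfg.embed_dim)
        self.ln2 = LayerNorm(cfg.embed_dim)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.ln1(x + self.drop(self.attn(x, x), rng))
        return self.ln2(h + self.drop(self.ffn(h), rng))


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    return np.log(np.expm1(y))


class Mamba2Block(Module):
    """Gated state-space block with data-dependent (a, B, C).

    Input projection (expansion 1) -> kernel-1 depthwise convolution ->
    SiLU -> per-timestep decay/input/output generation -> chunked SSD ->
    SiLU-gated output projection, with residual connection and post-norm.
    The decay is ``a_t = exp(-dt_t * softplus(a_base))`` with
    ``dt_t = softplus(dt_proj(u) + dt_bias)``, the scalar-times-identity
    structure that makes the semiseparable factorization valid.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, H = cfg.embed_dim, cfg.heads
        self.cfg = cfg
        # the expansion-1 input projection, split into the SSM branch and
        # the gate branch
        self.u_proj = Linear(d, cfg.expansion * d, rng)
        self.z_proj = Linear(d, cfg.expansion * d, rng)
        self.conv_w = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.conv_b = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self.dt_proj = Linear(d, H, rng)
        self.dt_bias = Tensor(
            _inv_softplus(rng.uniform(1e-3, 1e-1, size=H)).astype(DTYPE),
            requires_grad=True,
        )
        self.a_base = Tensor(rng.uniform(0.5, 2.5, size=H).astype(DTYPE), requires_grad=True)
        self.b_proj = Linear(d, cfg.ssm_state_dim, rng)
        self.c_proj = Linear(d, cfg.ssm_state_dim, rng)
        self.out_proj = Linear(d, d, rng)
        self.ln = LayerNorm(d)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.cfg
        b, T, d = x.shape
        H = cfg.heads
        P = d // H
        u = self.u_proj(x)
        z = self.z_proj(x)
        u = (u * self.conv_w + self.conv_b).silu()
        dt = (self.dt_proj(u) + self.dt_bias).softplus()  # (b, T, H)
        a = (-(dt * self.a_base.softplus())).exp()  # in (0, 1)
        B = self.b_proj(u)
        C = self.c_proj(u)
        y = _ssd_tensor(u.reshape(b, T, H, P), a, B, C, cfg.chunk_size)
        y = y.reshape(b, T, d) * z.silu()
        out = self.drop(self.out_proj(y), rng)
        return self.ln(x + out)


class CrossAttentionExchange(Module):
    """Bidirectional cross-view attention, both directions computed from the
    pre-exchange features and added residually (symmetric, order-free)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.f_from_l = MultiheadAttention(cfg.embed_dim, cfg.heads, rng)
        self.l_from_f = MultiheadAttention(cfg.embed_dim, cfg.heads, rng)
        self.ln_f = LayerNorm(cfg.embed_dim)
        self.ln_l = LayerNorm(cfg.embed_dim)
        self.drop = Dropout(cfg.dropout)

    def __call__(
        self, f: Tensor, l: Tensor, rng: np.random.Generator | None = None
    ) -> tuple[Tensor, Tensor]:
        f_new = self.ln_f(f + self.drop(self.f_from_l(f, l), rng))
        l_new = self.ln_l(l + self.drop(self.l_from_f(l, f), rng))
        return f_new, l_new


class CMSANet(Module):
    """Dual-stream fusion classifier.

    Layer ordering: self-attention at layers 1 and 3, Mamba-2 at layers 2
    and 4 (the streams alternate block types), each followed by a
    cross-attention exchange. Final per-stream features are mean-pooled
    over time, concatenated and classified by a linear + softmax head.
    """

    def __init__(self, cfg: ModelConfig = ModelConfig(), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.blocks_f: list[Module] = []
        self.blocks_l: list[Module] = []
        self.exchanges: list[CrossAttentionExchange] = []
        for i in range(cfg.depth):
            block_cls = SelfAttentionBlock if i % 2 == 0 else Mamba2Block
            self.blocks_f.append(block_cls(cfg, rng))
            self.blocks_l.append(block_cls(cfg, rng))
            self.exchanges.append(CrossAttentionExchange(cfg, rng))
        self.classifier = Linear(2 * cfg.embed_dim, 2, rng)

    def forward(
        self,
        frontal: np.ndarray | Tensor,
        lateral: np.ndarray | Tensor,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, list[Tensor], list[Tensor]]:
        """Return (class probabilities (b, 2), per-layer features per stream).

        ``rng`` enables dropout (training); None gives the deterministic
        inference pass.
        """
        f = frontal if isinstance(frontal, Tensor) else Tensor(np.asarray(frontal, dtype=DTYPE))
        l = lateral if isinstance(lateral, Tensor) else Tensor(np.asarray(lateral, dtype=DTYPE))
        if f.ndim == 2:
            f = f.reshape(1, *f.shape)
        if l.ndim == 2:
            l = l.reshape(1, *l.shape)
        if f.shape[-1] != self.cfg.embed_dim or l.shape[-1] != self.cfg.embed_dim:
            raise ValueError(
                f"inputs must have {self.cfg.embed_dim} features, got "
                f"{f.shape[-1]} / {l.shape[-1]}"
            )
        feats_f: list[Tensor] = []
        feats_l: list[Tensor] = []
        for bf, bl, ex in zip(self.blocks_f, self.blocks_l, self.exchanges):
            f = bf(f, rng)
            l = bl(l, rng)
            f, l = ex(f, l, rng)
            feats_f.append(f)
            feats_l.append(l)
        pooled = concat([f.mean(axis=1), l.mean(axis=1)], axis=-1)  # (b, 2d)
        probs = self.classifier(pooled).softmax(axis=-1)
        return probs, feats_f, feats_l

    __call__ = forward


def cmsa_forward(
    frontal: np.ndarray, lateral: np.ndarray, model: CMSANet
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """NumPy-facing inference pass: probabilities + per-layer stream features."""
    probs, ff, fl = model.forward(frontal, lateral, rng=None)
    return probs.data, [t.data for t in ff], [t.data for t in fl]


# --------------------------------------------------------- checkpointing

CHECKPOINT_SCHEMA = 1


def save_checkpoint(path, model: CMSANet, preprocessing: dict | None = None) -> None:
    """Single-file archive: weights + ModelConfig + preprocessing manifest."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.cfg),
        "preprocessing": preprocessing or {},
    }
    arrays = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[CMSANet, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        cfg = ModelConfig(**meta["config"])
        model = CMSANet(cfg)
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__meta__"})
    return model, meta.get("preprocessing", {})
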