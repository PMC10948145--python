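"""The Conv-Transformer network graph: time-distributed convolutions,
self-attention over frame tokens, MLP head with 2-way softmax."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ._layers import (
    BatchNorm2d, Conv2d, Dropout, Layer, LayerNorm, Linear, MaxPool2d,
    MultiHeadSelfAttention, ReLU, _softmax_lastaxis,
)


@dataclass
class ModelConfig:
    """Architecture of the sequence classifier.

    Defaults follow the full-scale design: three convolutional blocks of
    widths 64/128/256 (3x3 kernels, size-preserving padding, ReLU, batch
    norm, dropout 0.3, 2x2 max pooling), per-frame features projected to
    ``token_dim``-dimensional tokens, four attention blocks with six heads,
    and a 1024/512/128/64 MLP ending in a 2-way softmax.  ``small()`` gives
    a reduced preset for CPU-scale experiments.
    """

    clip_len: int = 5
    input_size: int = 59
    conv_widths: Tuple[int, ...] = (64, 128, 256)
    conv_kernel: int = 3
    conv_dropout: float = 0.3
    token_dim: int = 240  # divisible by n_heads
    n_heads: int = 6
    n_attention_blocks: int = 4
    ff_dim: Optional[int] = None  # default 2 * token_dim
    attn_dropout: float = 0.1
    pool: str = "concat"  # "concat" (order-preserving) | "mean"
    mlp_widths: Tuple[int, ...] = (1024, 512, 128, 64)
    mlp_dropout: float = 0.3

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.conv_widths + self.mlp_widths):
            raise ValueError("layer widths must be positive")
        for p in (self.conv_dropout, self.mlp_dropout, self.attn_dropout):
            if not 0 <= p < 1:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.pool not in ("concat", "mean"):
            raise ValueError("pool must be 'concat' or 'mean'")
        if self.token_dim % self.n_heads != 0:
            raise ValueError("token_dim must be divisible by n_heads")
        s = self.input_size
        for _ in self.conv_widths:
            s //= 2
            if s < 1:
                raise ValueError("pooling reduces spatial size below 1")

    @classmethod
    def small(cls) -> "ModelConfig":
        """Desk-scale preset: same topology, reduced widths."""
        return cls(conv_widths=(6, 12, 24), token_dim=48, n_heads=4,
                   n_attention_blocks=2, mlp_widths=(128, 64))


class _TransformerBlock:
    """Pre-norm block: x + Drop(MHSA(LN(x))); then x + Drop(FFN(LN(x)))."""

    def __init__(self, d, n_heads, ff_dim, p_drop, rng, drop_rng, dtype):
        self.ln1 = LayerNorm(d, dtype=dtype)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng=rng, dtype=dtype)
        self.drop1 = Dropout(p_drop, rng=drop_rng)
        self.ln2 = LayerNorm(d, dtype=dtype)
        self.ff1 = Linear(d, ff_dim, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.ff2 = Linear(ff_dim, d, rng=rng, scale=np.sqrt(1.0 / ff_dim), dtype=dtype)
        self.drop2 = Dropout(p_drop, rng=drop_rng)

    def layers(self) -> List[Layer]:
        return [self.ln1, self.attn, self.drop1, self.ln2, self.ff1, self.ff2, self.drop2]

    def forward(self, x, train):
        a = x + self.drop1.forward(
            self.attn.forward(self.ln1.forward(x, train), train), train)
        h = self.ff2.forward(
            self.relu.forward(self.ff1.forward(self.ln2.forward(a, train), train), train),
            train)
        return a + self.drop2.forward(h, train)

    def backward(self, dy):
        dh = self.drop2.backward(dy)
        da = self.ln2.backward(
            self.ff1.backward(self.relu.backward(self.ff2.backward(dh)))) + dy
        datt = self.drop1.backward(da)
        dx = self.ln1.backward(self.attn.backward(datt)) + da
        return dx


class ConvTransformerNet:
    """Forward/backward graph; parameters live in the member layers."""

    def __init__(self, config: ModelConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.drop_rng = np.random.default_rng(seed + 1)

        c = config
        self.conv_blocks = []
        c_in = 1
        s = c.input_size
        for bi, w in enumerate(c.conv_widths):
            block = {
                "conv": Conv2d(c_in, w, c.conv_kernel, rng=rng, dtype=dtype,
                               needs_input_grad=bi > 0),
                "relu": ReLU(),
                "bn": BatchNorm2d(w, dtype=dtype),
                "drop": Dropout(c.conv_dropout, rng=self.drop_rng),
                "pool": MaxPool2d(),
            }
            self.conv_blocks.append(block)
            c_in = w
            s //= 2
        self.feat_dim = c.conv_widths[-1] * s * s
        self._feat_hw = s
        self.proj = Linear(self.feat_dim, c.token_dim, rng=rng,
                           scale=np.sqrt(1.0 / self.feat_dim), dtype=dtype)
        self.pos_embed = rng.normal(0, 0.02, (c.clip_len, c.token_dim)).astype(dtype)
        self.pos_embed_grad = np.zeros_like(self.pos_embed)
        ff = c.ff_dim or 2 * c.token_dim
        self.blocks = [
            _TransformerBlock(c.token_dim, c.n_heads, ff, c.attn_dropout,
                              rng, self.drop_rng, dtype)
            for _ in range(c.n_attention_blocks)
        ]
        self.final_ln = LayerNorm(c.token_dim, dtype=dtype)
        self.mlp = []
        d_in = c.token_dim * (c.clip_len if c.pool == "concat" else 1)
        for w in c.mlp_widths:
            self.mlp.append({
                "lin": Linear(d_in, w, rng=rng, dtype=dtype),
                "relu": ReLU(),
                "drop": Dropout(c.mlp_dropout, rng=self.drop_rng),
            })
            d_in = w
        self.head = Linear(d_in, 2, rng=rng, scale=np.sqrt(1.0 / d_in), dtype=dtype)

    # ------------------------------------------------------------------
    def parameters(self):
        """Yield (owner_key, name, param, grad_getter) for the optimizer."""
        out = []
        for i, b in enumerate(self.conv_blocks):
            for ln in ("conv", "bn"):
                out.append((f"conv{i}.{ln}", b[ln]))
        out.append(("proj", self.proj))
        for i, blk in enumerate(self.blocks):
            for j, lyr in enumerate(blk.layers()):
                if lyr.params:
                    out.append((f"block{i}.{j}", lyr))
        out.append(("final_ln", self.final_ln))
        for i, m in enumerate(self.mlp):
            out.append((f"mlp{i}", m["lin"]))
        out.append(("head", self.head))
        return out

    def n_parameters(self) -> int:
        n = self.pos_embed.size
        for _, lyr in self.parameters():
            n += sum(p.size for p in lyr.params.values())
        return n

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, K, H, W) scaled to [0, 1]; returns logits (N, 2)."""
        N, K, H, W = x.shape
        h = x.reshape(N * K, H, W, 1).astype(self.dtype, copy=False)
        for b in self.conv_blocks:
            h = b["conv"].forward(h, train)
            h = b["relu"].forward(h, train)
            h = b["bn"].forward(h, train)
            h = b["drop"].forward(h, train)
            h = b["pool"].forward(h, train)
        self._conv_out_shape = h.shape
        h = h.reshape(N * K, -1)
        tok = self.proj.forward(h, train).reshape(N, K, -1)
        tok = tok + self.pos_embed[None]
        for blk in self.blocks:
            tok = blk.forward(tok, train)
        tok = self.final_ln.forward(tok, train)
        self._K = K
        if self.config.pool == "concat":  # order-preserving sequence pooling
            z = tok.reshape(N, -1)
        else:
            z = tok.mean(axis=1)
        for m in self.mlp:
            z = m["drop"].forward(m["relu"].forward(m["lin"].forward(z, train), train), train)
        return self.head.forward(z, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head.backward(dlogits)
        for m in reversed(self.mlp):
            dz = m["lin"].backward(m["relu"].backward(m["drop"].backward(dz)))
        N = dz.shape[0]
        K = self._K
        if self.config.pool == "concat":
            dtok = dz.reshape(N, K, -1)
        else:
            dtok = np.repeat(dz[:, None, :], K, axis=1) / K
        dtok = self.final_ln.backward(dtok)
        for blk in reversed(self.blocks):
            dtok = blk.backward(dtok)
        self.pos_embed_grad = dtok.sum(axis=0)
        dh = self.proj.backward(dtok.reshape(N * K, -1))
        dh = dh.reshape(self._conv_out_shape)
        for b in reversed(self.conv_blocks):
            dh = b["pool"].backward(dh)
            dh = b["drop"].backward(dh)
            dh = b["bn"].backward(dh)
            dh = b["relu"].backward(dh)
            dh = b["conv"].backward(dh)

    # ------------------------------------------------------------------
    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax_lastaxis(self.forward(x, train=False))

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray):
        """Two-class cross-entropy; returns (loss, accuracy) and backprops."""
        logits = self.forward(x, train=True)
        probs = _softmax_lastaxis(logits.astype(np.float64))
        n = len(y)
        loss = -np.log(np.maximum(probs[np.arange(n), y], 1e-12)).mean()
        acc = float((probs.argmax(axis=1) == y).mean())
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        self.backward((dlogits / n).astype(self.dtype))
        return float(loss), acc

    # ------------------------------------------------------------------
    def state_dict(self):
        state = {"pos_embed": self.pos_embed.copy()}
        for key, lyr in self.parameters():
            for name, p in lyr.params.items():
                state[f"{key}:{name}"] = p.copy()
            if isinstance(lyr, BatchNorm2d):
                state[f"{key}:running_mean"] = lyr.running_mean.copy()
                state[f"{key}:running_var"] = lyr.running_var.copy()
        return state

    def load_state_dict(self, state):
        self.pos_embed = state["pos_embed"].copy()
        for key, lyr in self.parameters():
            for name in lyr.params:
                lyr.params[name] = state[f"{key}:{name}"].copy()
            if isinstance(lyr, BatchNorm2d):
                lyr.running_mean = state[f"{key}:running_mean"].copy()
                lyr.running_var = state[f"{key}:running_var"].copy()


class Adam:
    """Adam with bias correction; one state slot per parameter array."""

    def __init__(self, net: ConvTransformerNet, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: Optional[float] = 5.0):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {}
        self.v = {}

    def _grad_scale(self) -> float:
        if self.clip_norm is None:
            return 1.0
        total = float(np.sum(self.net.pos_embed_grad.astype(np.float64) ** 2))
        for _, lyr in self.net.parameters():
            for name, g in lyr.grads.items():
                total += float(np.sum(g.astype(np.float64) ** 2))
        norm = np.sqrt(total)
        return 1.0 if norm <= self.clip_norm else self.clip_norm / norm

    def step(self) -> None:
        self.t += 1
        scale = self._grad_scale()
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t

        def upd(key, p, g):
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

        upd("pos_embed", self.net.pos_embed, scale * self.net.pos_embed_grad)
        for key, lyr in self.net.parameters():
            for name, p in lyr.params.items():
                g = lyr.grads.get(name)
                if g is not None:
                    upd(f"{key}:{name}", p, scale * g.astype(p.dtype, copy=False))
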