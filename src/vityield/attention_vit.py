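"""Multi-head self-attention and the ViT image encoder.

The attention core follows the standard scaled dot-product formulation; the
ViT splits an image into non-overlapping P x P patches (row-major), embeds
them linearly, prepends a learnable class token, adds learnable positional
embeddings and applies pre-LN transformer blocks. The image feature is the
layer-normed class token after the last block.

Per-head projections are D x d_k with d_k = floor(D / h); the concatenated
heads (h * d_k wide) are projected back to D by W_O, which also covers the
case where D is not divisible by h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidArgumentError
from .nn import Linear, LayerNorm, Module, Parameter, Tensor

__all__ = [
    "ViTConfig", "scaled_dot_product_attention", "attention_weights",
    "MultiHeadAttention", "multi_head_attention", "patchify",
    "patchify_embed", "TransformerBlock", "vit_layer", "ViT", "vit_encode",
]


@dataclass(frozen=True)
class ViTConfig:
    image_size: int = 128
    patch_size: int = 16
    embed_dim: int = 128
    depth: int = 2
    heads: int = 3
    mlp_hidden: int | None = None  # defaults to 4 * embed_dim
    channels: int = 3

    def __post_init__(self):
        if self.depth < 1 or self.heads < 1:
            raise ConfigurationError("depth and heads must be >= 1")
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image size {self.image_size} not divisible by patch "
                f"size {self.patch_size}")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def d_k(self) -> int:
        return self.embed_dim // self.heads

    @property
    def hidden(self) -> int:
        return self.mlp_hidden if self.mlp_hidden is not None \
            else 4 * self.embed_dim


# ------------------------------------------------------------------ attention

def scaled_dot_product_attention(Q, K, V, d_k: int | None = None):
    """softmax(Q K^T / sqrt(d_k)) V on the trailing two axes.

    Accepts numpy arrays or Tensors; leading axes broadcast (batch, head).
    """
    Q, K, V = Tensor._wrap(Q), Tensor._wrap(K), Tensor._wrap(V)
    if Q.shape[-1] != K.shape[-1]:
        raise InvalidArgumentError(
            f"Q and K widths differ: {Q.shape[-1]} vs {K.shape[-1]}")
    if K.shape[-2] != V.shape[-2]:
        raise InvalidArgumentError(
            f"K and V row counts differ: {K.shape[-2]} vs {V.shape[-2]}")
    if d_k is None:
        d_k = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    return scores.softmax(axis=-1) @ V


def attention_weights(Q, K, d_k: int | None = None) -> np.ndarray:
    """The softmax attention matrix alone (for diagnostics/tests)."""
    Q, K = Tensor._wrap(Q), Tensor._wrap(K)
    if d_k is None:
        d_k = Q.shape[-1]
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    return scores.softmax(axis=-1).numpy()


class MultiHeadAttention(Module):
    """h independent heads with D x d_k projections, concatenated and
    projected back to D by ``W_O`` ((h * d_k) x D)."""

    def __init__(self, embed_dim: int, heads: int, rng: np.random.Generator):
        self.embed_dim = embed_dim
        self.heads = heads
        self.d_k = embed_dim // heads
        if self.d_k < 1:
            raise ConfigurationError("heads exceed embedding width")
        shape = (embed_dim, self.d_k)
        self.W_q = [Parameter(nn.fan_in_uniform(rng, shape)) for _ in range(heads)]
        self.W_k = [Parameter(nn.fan_in_uniform(rng, shape)) for _ in range(heads)]
        self.W_v = [Parameter(nn.fan_in_uniform(rng, shape)) for _ in range(heads)]
        self.W_O = Parameter(
            nn.fan_in_uniform(rng, (heads * self.d_k, embed_dim)))

    def forward(self, a: Tensor) -> Tensor:
        a = Tensor._wrap(a)
        if a.shape[-1] != self.embed_dim:
            raise InvalidArgumentError(
                f"token width {a.shape[-1]} != embed_dim {self.embed_dim}")
        heads = []
        for i in range(self.heads):
            q, k, v = a @ self.W_q[i], a @ self.W_k[i], a @ self.W_v[i]
            heads.append(scaled_dot_product_attention(q, k, v, self.d_k))
        return nn.concatenate(heads, axis=-1) @ self.W_O

    def head_attention_maps(self, a) -> list[np.ndarray]:
        a = Tensor._wrap(a)
        return [attention_weights(a @ self.W_q[i], a @ self.W_k[i], self.d_k)
                for i in range(self.heads)]


def multi_head_attention(a, W_q_list, W_k_list, W_v_list, W_O):
    """Functional multi-head attention from explicit per-head matrices."""
    a = Tensor._wrap(a)
    h = len(W_q_list)
    d_k = Tensor._wrap(W_q_list[0]).shape[-1]
    W_O = Tensor._wrap(W_O)
    if W_O.shape[0] != h * d_k:
        raise ConfigurationError(
            f"W_O rows {W_O.shape[0]} != h*d_k = {h * d_k}")
    heads = []
    for Wq, Wk, Wv in zip(W_q_list, W_k_list, W_v_list):
        Wq, Wk, Wv = map(Tensor._wrap, (Wq, Wk, Wv))
        heads.append(scaled_dot_product_attention(a @ Wq, a @ Wk, a @ Wv, d_k))
    return nn.concatenate(heads, axis=-1) @ W_O


# ----------------------------------------------------------------- patchifying

def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Row-major (top-left to bottom-right) patch flattening.

    image: (H, W, C) or (B, H, W, C) -> (N, P*P*C) or (B, N, P*P*C).
    """
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 3
    if squeeze:
        image = image[None]
    b, h, w, c = image.shape
    p = patch_size
    if h % p or w % p:
        raise InvalidArgumentError(
            f"image {h}x{w} not divisible by patch size {p}")
    patches = image.reshape(b, h // p, p, w // p, p, c) \
                   .transpose(0, 1, 3, 2, 4, 5) \
                   .reshape(b, (h // p) * (w // p), p * p * c)
    return patches[0] if squeeze else patches


def patchify_embed(image, E, E_pos, class_token, patch_size: int) -> Tensor:
    """z_0 = [class; x_p^1 E; ...; x_p^N E] + E_pos.

    ``E`` is (P^2*C) x D, ``E_pos`` is (N+1) x D, ``class_token`` is D.
    Works on a single image or a batch.
    """
    E, E_pos, cls = Tensor._wrap(E), Tensor._wrap(E_pos), Tensor._wrap(class_token)
    patches = patchify(image, patch_size)
    batched = patches.ndim == 3
    tokens = Tensor(patches) @ E  # (..., N, D)
    n = tokens.shape[-2]
    if E_pos.shape[0] != n + 1:
        raise InvalidArgumentError(
            f"E_pos has {E_pos.shape[0]} rows, expected N+1 = {n + 1}")
    d = tokens.shape[-1]
    if batched:
        b = tokens.shape[0]
        cls_row = cls.reshape(1, 1, d) * Tensor(np.ones((b, 1, 1)))
        z = nn.concatenate([cls_row, tokens], axis=1)
    else:
        z = nn.concatenate([cls.reshape(1, d), tokens], axis=0)
    return z + E_pos


# -------------------------------------------------------------------- blocks

class TransformerBlock(Module):
    """Pre-LN block: z' = MHA(LN(z)) + z; out = MLP(LN(z')) + z'."""

    def __init__(self, embed_dim: int, heads: int, mlp_hidden: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        self.ln1 = LayerNorm(embed_dim)
        self.attn = MultiHeadAttention(embed_dim, heads, rng)
        self.ln2 = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, mlp_hidden, rng)
        self.fc2 = Linear(mlp_hidden, embed_dim, rng)
        self.dropout = dropout

    def forward(self, z: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        z = self.attn(self.ln1(z)) + z
        hmid = self.fc1(self.ln2(z)).gelu()
        if training and self.dropout > 0:
            hmid = hmid.dropout(self.dropout, rng, training)
        return self.fc2(hmid) + z


def vit_layer(z, block: TransformerBlock) -> Tensor:
    """Apply one transformer block (functional alias)."""
    return block(Tensor._wrap(z))


# ----------------------------------------------------------------------- ViT

def _trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02):
    x = rng.normal(0.0, sd, size=shape)
    return np.clip(x, -2 * sd, 2 * sd)


class ViT(Module):
    """ViT image encoder; ``encode`` returns the D-dim class-token feature."""

    def __init__(self, config: ViTConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.E = Parameter(nn.fan_in_uniform(
            rng, (c.patch_size ** 2 * c.channels, c.embed_dim)))
        self.class_token = Parameter(_trunc_normal(rng, (c.embed_dim,)))
        self.E_pos = Parameter(
            _trunc_normal(rng, (c.n_patches + 1, c.embed_dim)))
        self.blocks = [
            TransformerBlock(c.embed_dim, c.heads, c.hidden, rng)
            for _ in range(c.depth)
        ]
        self.ln_out = LayerNorm(c.embed_dim)

    def forward(self, images, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        z = patchify_embed(images, self.E, self.E_pos, self.class_token,
                           self.config.patch_size)
        for blk in self.blocks:
            z = blk(z, training=training, rng=rng)
        cls = z[:, 0, :] if z.ndim == 3 else z[0, :]
        return self.ln_out(cls)

    def attention_maps(self, images) -> list[list[np.ndarray]]:
        z = patchify_embed(images, self.E, self.E_pos, self.class_token,
                           self.config.patch_size)
        maps = []
        for blk in self.blocks:
            maps.append(blk.attn.head_attention_maps(blk.ln1(z)))
            z = blk(z)
        return maps


def vit_encode(image, model: ViT) -> np.ndarray:
    """Encode one image (or a batch) to its D-dim feature, as numpy."""
    return model(image).numpy()
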