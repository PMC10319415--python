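"""Encoder-only transformer over per-timestamp image features.

A dense input layer maps each timestamp's feature to the model width,
sine/cosine positional encodings are added element-wise, a stack of pre-LN
multi-head blocks attends across timestamps bidirectionally, and the
timestep outputs are mean-pooled and projected to the 128-d image
representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention_vit import TransformerBlock
from .errors import ConfigurationError, InvalidArgumentError
from .nn import Linear, Module, Tensor

__all__ = [
    "TemporalConfig", "sinusoidal_positional_encoding", "TemporalEncoder",
    "encode_sequence",
]


@dataclass(frozen=True)
class TemporalConfig:
    embed_dim: int = 128
    depth: int = 3
    heads: int = 5
    out_dim: int = 128
    mlp_hidden: int | None = None

    @property
    def hidden(self) -> int:
        return self.mlp_hidden if self.mlp_hidden is not None \
            else 4 * self.embed_dim


def sinusoidal_positional_encoding(T: int, D: int) -> np.ndarray:
    """PE[t, 2i] = sin(t / 10000^(2i/D)); PE[t, 2i+1] = cos(t / 10000^(2i/D))."""
    if D % 2 != 0:
        raise ConfigurationError("positional-encoding width must be even")
    t = np.arange(T)[:, None]
    i = np.arange(D // 2)[None, :]
    angle = t / np.power(10000.0, 2.0 * i / D)
    pe = np.empty((T, D))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class TemporalEncoder(Module):
    def __init__(self, config: TemporalConfig, rng: np.random.Generator,
                 use_positional_encoding: bool = True):
        self.config = config
        d = config.embed_dim
        self.input_proj = Linear(d, d, rng)
        self.blocks = [
            TransformerBlock(d, config.heads, config.hidden, rng)
            for _ in range(config.depth)
        ]
        self.output_proj = Linear(d, config.out_dim, rng)
        self.use_positional_encoding = use_positional_encoding

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """x: (T, D) or (B, T, D) -> (out_dim,) or (B, out_dim)."""
        x = Tensor._wrap(x)
        if x.shape[-2] == 0:
            raise InvalidArgumentError("empty time series")
        if x.shape[-1] != self.config.embed_dim:
            raise InvalidArgumentError(
                f"feature width {x.shape[-1]} != {self.config.embed_dim}")
        z = self.input_proj(x)
        if self.use_positional_encoding:
            z = z + Tensor(sinusoidal_positional_encoding(
                z.shape[-2], self.config.embed_dim))
        for blk in self.blocks:
            z = blk(z, training=training, rng=rng)
        pooled = z.mean(axis=-2)
        return self.output_proj(pooled)


def encode_sequence(features, model: TemporalEncoder) -> np.ndarray:
    """Encode a (T, D) feature series to the 128-d representation, as numpy."""
    return model(features).numpy()
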