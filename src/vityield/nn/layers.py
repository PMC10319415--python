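"""Layer building blocks on top of the autodiff :class:`Tensor`.

Modules hold named parameters; ``named_parameters`` walks the tree and
yields dotted paths, which is also the checkpoint key format.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Linear", "LayerNorm", "Sequential",
    "conv2d", "max_pool2d", "fan_in_uniform",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def fan_in_uniform(rng: np.random.Generator, shape, fan_in: int | None = None):
    """He-style fan-in uniform init used for dense and conv weights."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class; parameters and submodules are discovered by attribute."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(fan_in_uniform(rng, (d_in, d_out), fan_in=d_in))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, eps=self.eps)


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


# ---------------------------------------------------------------- conv / pool

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int):
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh, ow = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    cols = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # (b, c, oh, ow, kh, kw) -> (b, oh, ow, c*kh*kw)
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh, ow, c * kh * kw)
    return cols, oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, pad: int = 1) -> Tensor:
    """2-D convolution, stride 1. x: (B,C,H,W); weight: (Cout, Cin, kh, kw)."""
    co, ci, kh, kw = weight.shape
    cols, oh, ow = _im2col(x.data, kh, kw, pad)
    b = x.shape[0]
    wmat = weight.data.reshape(co, ci * kh * kw).T  # (ckk, co)
    out = cols.reshape(-1, ci * kh * kw) @ wmat
    out = out.reshape(b, oh, ow, co).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def bwd(g):
        # g: (B, Cout, oh, ow)
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, co)
        gw = (cols.reshape(-1, ci * kh * kw).T @ gmat).T.reshape(weight.shape)
        gcols = (gmat @ wmat.T).reshape(b, oh, ow, ci, kh, kw)
        h, w = x.shape[2], x.shape[3]
        gx = np.zeros((b, ci, h + 2 * pad, w + 2 * pad))
        for i in range(kh):
            for j in range(kw):
                gx[:, :, i:i + oh, j:j + ow] += gcols[:, :, :, :, i, j] \
                    .transpose(0, 3, 1, 2)
        if pad:
            gx = gx[:, :, pad:-pad, pad:-pad]
        grads = [(x, gx), (weight, gw)]
        if bias is not None:
            grads.append((bias, g.sum(axis=(0, 2, 3))))
        return tuple(grads)

    return Tensor._make(out, parents, bwd)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.shape
    assert h % k == 0 and w % k == 0, "pooling needs divisible dims"
    xr = x.data.reshape(b, c, h // k, k, w // k, k)
    out = xr.max(axis=(3, 5))

    def bwd(g):
        mask = (xr == out[:, :, :, None, :, None])
        counts = mask.sum(axis=(3, 5), keepdims=True)
        gx = mask * (g[:, :, :, None, :, None] / counts)
        return ((x, gx.reshape(b, c, h, w)),)

    return Tensor._make(out, (x,), bwd)
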