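"""The wide-deep yield model and the four baseline architectures.

All models share one contract: ``preprocess`` turns a list of
:class:`~vityield.records.PlotRecord` into cached numpy inputs, and
``forward_batch`` maps a batch of those inputs to predicted yields on a
standardized target scale (``predict`` converts back to kg/ha). The
training loop in :mod:`vityield.train_eval` treats every model
interchangeably through this contract.

Fusion in the proposed model: per-timestamp element-wise product of the
plant and soil ViT features, a temporal transformer over the fused series,
then concatenation with the 16-d seed embedding feeding the dense head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .attention_vit import ViT, ViTConfig
from .errors import ConfigurationError, DataError, InvalidArgumentError
from .nn import Linear, Module, Parameter, Tensor, conv2d, max_pool2d
from .records import PlotRecord
from .segmentation import segment_plant_soil
from .temporal_transformer import TemporalConfig, TemporalEncoder

__all__ = [
    "SeedEncoder", "encode_seed", "Head", "ProposedModel", "BaselineSpec",
    "build_baseline", "fuse_features", "forward_proposed", "YieldModel",
    "ConvBackbone", "VGG16Backbone", "BiLSTM", "LSTMStack",
    "CnnLrModel", "CnnLstmModel", "VitLstmModel", "VitTModel",
]


# ------------------------------------------------------------------ seed branch

class SeedEncoder(Module):
    """One-hot seed combination -> three 16-unit ReLU dense layers."""

    def __init__(self, n_combos: int, rng: np.random.Generator,
                 width: int = 16, dropout: float = 0.25):
        self.n_combos = n_combos
        self.width = width
        self.dropout = dropout
        self.fc1 = Linear(n_combos, width, rng)
        self.fc2 = Linear(width, width, rng)
        self.fc3 = Linear(width, width, rng)

    def forward(self, combo_index, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        idx = np.atleast_1d(np.asarray(combo_index, dtype=int))
        if idx.min() < 0 or idx.max() >= self.n_combos:
            raise InvalidArgumentError(
                f"combo index out of range [0, {self.n_combos})")
        # one-hot @ W selects rows of W
        x = self.fc1.W[idx] + self.fc1.b
        x = x.relu()
        for layer in (self.fc2, self.fc3):
            x = layer(x).relu()
            if training and self.dropout > 0:
                x = x.dropout(self.dropout, rng, training)
        if np.isscalar(combo_index) or np.asarray(combo_index).ndim == 0:
            return x[0]
        return x


def encode_seed(combo_index: int, encoder: SeedEncoder) -> np.ndarray:
    """Encode one combo index to its 16-d embedding, as numpy."""
    return encoder(combo_index).numpy()


class Head(Module):
    """Three 128-unit ReLU dense layers (dropout 0.25) + linear output unit."""

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 width: int = 128, dropout: float = 0.25):
        self.fc1 = Linear(in_dim, width, rng)
        self.fc2 = Linear(width, width, rng)
        self.fc3 = Linear(width, width, rng)
        self.out = Linear(width, 1, rng)
        self.dropout = dropout

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        for layer in (self.fc1, self.fc2, self.fc3):
            x = layer(x).relu()
            if training and self.dropout > 0:
                x = x.dropout(self.dropout, rng, training)
        y = self.out(x)
        return y.reshape(y.shape[:-1]) if y.shape[-1] == 1 else y


# ------------------------------------------------------------------ base class

class YieldModel(Module):
    """Common fit/predict contract for the model zoo."""

    name = "base"
    input_size: int = 128
    use_seed_info: bool = True

    def __init__(self):
        self.y_mean = 0.0
        self.y_std = 1.0
        self.is_trained = False

    def set_target_scale(self, y_train):
        y = np.asarray(y_train, dtype=float)
        self.y_mean = float(y.mean())
        self.y_std = float(y.std()) or 1.0

    # -- subclass API -------------------------------------------------------
    def preprocess(self, records: list[PlotRecord]) -> dict:
        raise NotImplementedError

    def image_representation(self, data: dict, idx, training: bool = False,
                             rng: np.random.Generator | None = None) -> Tensor:
        """Image-branch feature v for a batch (before the seed concat)."""
        raise NotImplementedError

    def forward_batch(self, data: dict, idx, training: bool = False,
                      rng: np.random.Generator | None = None) -> Tensor:
        v = self.image_representation(data, idx, training=training, rng=rng)
        return self.head_forward(v, data["combo"][idx], training=training,
                                 rng=rng)

    def head_forward(self, v: Tensor, combo_index, training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        """Seed branch + head on a precomputed image representation."""
        if self.use_seed_info:
            f_seed = self.seed_encoder(combo_index, training=training, rng=rng)
        else:
            f_seed = Tensor(np.zeros((v.shape[0], 0)))
        fused = nn.concatenate([v, f_seed], axis=-1)
        return self.head(fused, training=training, rng=rng)

    # -- shared -------------------------------------------------------------
    def predict(self, records_or_data, batch_size: int = 32) -> np.ndarray:
        data = records_or_data if isinstance(records_or_data, dict) \
            else self.preprocess(records_or_data)
        n = len(data["y"])
        out = np.empty(n)
        for s in range(0, n, batch_size):
            idx = np.arange(s, min(s + batch_size, n))
            out[idx] = self.forward_batch(data, idx).numpy()
        return out * self.y_std + self.y_mean

    def l2_penalty(self) -> Tensor | None:
        """Optional extra loss term (used by the CNN-LR baseline)."""
        return None

    @staticmethod
    def _stack_images(records: list[PlotRecord]) -> np.ndarray:
        t_counts = {r.n_timestamps for r in records}
        if len(t_counts) != 1:
            raise DataError(f"inconsistent timestamp counts: {t_counts}")
        missing = [r.plot_id for r in records if any(
            im is None for im in r.images)]
        if missing:
            raise DataError(f"missing timestamp image for plots {missing}")
        return np.stack([np.stack([np.asarray(im, dtype=np.float32)
                                   for im in r.images]) for r in records])

    @staticmethod
    def _labels(records):
        return (np.array([r.combo_index for r in records], dtype=int),
                np.array([r.yield_kg_ha for r in records], dtype=float))


# ----------------------------------------------------------------- fusion ops

def fuse_features(f_plant_seq, f_soil_seq, f_seed, temporal: TemporalEncoder,
                  head: Head, training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """phi = Head([TemporalEncoder(f_plant (*) f_soil), f_seed]).

    ``f_plant_seq``/``f_soil_seq``: (T, D) or (B, T, D); ``f_seed``: (16,)
    or (B, 16). The (*) is the element-wise (Hadamard) product per
    timestamp; "+" of the wide and deep branches is concatenation.
    """
    fp, fs = Tensor._wrap(f_plant_seq), Tensor._wrap(f_soil_seq)
    if fp.shape != fs.shape:
        raise InvalidArgumentError(
            f"plant/soil feature shapes differ: {fp.shape} vs {fs.shape}")
    m = fp * fs
    v = temporal(m, training=training, rng=rng)
    f_seed = Tensor._wrap(f_seed)
    fused = nn.concatenate([v, f_seed], axis=-1)
    return head(fused, training=training, rng=rng)


class ProposedModel(YieldModel):
    """Dual-ViT (plant/soil streams) + temporal transformer + seed branch."""

    name = "proposed"

    def __init__(self, vit_config: ViTConfig | None = None,
                 temporal_config: TemporalConfig | None = None,
                 n_combos: int = 51, seed: int = 0, dropout: float = 0.25,
                 use_seed_info: bool = True):
        super().__init__()
        rng = np.random.default_rng([seed, 11])
        self.vit_config = vit_config or ViTConfig()
        d = self.vit_config.embed_dim
        self.temporal_config = temporal_config or TemporalConfig(embed_dim=d)
        if self.temporal_config.embed_dim != d:
            raise ConfigurationError("temporal width must match ViT width")
        self.input_size = self.vit_config.image_size
        self.use_seed_info = use_seed_info
        # separate streams: the two ViTs do not share weights
        self.plant_vit = ViT(self.vit_config, rng)
        self.soil_vit = ViT(self.vit_config, rng)
        self.temporal = TemporalEncoder(self.temporal_config, rng)
        self.seed_encoder = SeedEncoder(n_combos, rng, dropout=dropout) \
            if use_seed_info else None
        head_in = self.temporal_config.out_dim + (16 if use_seed_info else 0)
        self.head = Head(head_in, rng, dropout=dropout)

    def preprocess(self, records: list[PlotRecord]) -> dict:
        images = self._stack_images(records)  # (N, T, H, W, 3)
        plant = np.empty_like(images)
        soil = np.empty_like(images)
        for i in range(images.shape[0]):
            for t in range(images.shape[1]):
                pair = segment_plant_soil(images[i, t])
                plant[i, t] = pair.plant_image
                soil[i, t] = pair.soil_image
        combo, y = self._labels(records)
        return {"plant": plant, "soil": soil, "combo": combo, "y": y}

    def image_representation(self, data, idx, training=False, rng=None) -> Tensor:
        plant = np.asarray(data["plant"][idx], dtype=np.float64)
        soil = np.asarray(data["soil"][idx], dtype=np.float64)
        b, t = plant.shape[:2]
        fp = self.plant_vit(plant.reshape((b * t,) + plant.shape[2:]),
                            training=training, rng=rng)
        fs = self.soil_vit(soil.reshape((b * t,) + soil.shape[2:]),
                           training=training, rng=rng)
        d = fp.shape[-1]
        m = fp.reshape(b, t, d) * fs.reshape(b, t, d)
        return self.temporal(m, training=training, rng=rng)


def forward_proposed(record: PlotRecord, model: ProposedModel) -> float:
    """Predict one plot's yield (kg/ha) end to end (segment -> encode -> fuse)."""
    data = model.preprocess([record])
    return float(model.predict(data)[0])


# ------------------------------------------------------------------ backbones

class ConvBackbone(Module):
    """Small 4-conv-block CNN stand-in for desk-scale experiments."""

    def __init__(self, image_size: int, rng: np.random.Generator,
                 out_dim: int = 128, widths=(8, 16, 32, 64)):
        self.widths = widths
        chans = [3] + list(widths)
        self.convs = [
            Parameter(nn.fan_in_uniform(rng, (chans[i + 1], chans[i], 3, 3),
                                        fan_in=chans[i] * 9))
            for i in range(len(widths))
        ]
        self.conv_biases = [Parameter(np.zeros(w)) for w in widths]
        final = image_size // (2 ** len(widths))
        self.fc = Linear(final * final * widths[-1], out_dim, rng)
        self.out_dim = out_dim

    def forward(self, images: Tensor) -> Tensor:
        x = Tensor._wrap(images).transpose(0, 3, 1, 2)  # NHWC -> NCHW
        for w, b in zip(self.convs, self.conv_biases):
            x = max_pool2d(conv2d(x, w, b, pad=1).relu(), 2)
        x = x.reshape(x.shape[0], -1)
        return self.fc(x).relu()


class VGG16Backbone(Module):
    """VGG-16 layout: 13 conv layers in 5 pooled blocks + 3 dense layers.

    Dense widths are scaled down from the classification original to keep a
    from-scratch regression backbone tractable on CPU.
    """

    BLOCKS = ((64, 64), (128, 128), (256, 256, 256),
              (512, 512, 512), (512, 512, 512))

    def __init__(self, image_size: int, rng: np.random.Generator,
                 out_dim: int = 128, fc_widths=(512, 256)):
        self.convs, self.conv_biases = [], []
        c_in = 3
        for block in self.BLOCKS:
            for c_out in block:
                self.convs.append(Parameter(nn.fan_in_uniform(
                    rng, (c_out, c_in, 3, 3), fan_in=c_in * 9)))
                self.conv_biases.append(Parameter(np.zeros(c_out)))
                c_in = c_out
        final = image_size // (2 ** len(self.BLOCKS))
        dims = [final * final * 512, *fc_widths, out_dim]
        self.fcs = [Linear(dims[i], dims[i + 1], rng) for i in range(3)]
        self.out_dim = out_dim

    def forward(self, images: Tensor) -> Tensor:
        x = Tensor._wrap(images).transpose(0, 3, 1, 2)
        k = 0
        for block in self.BLOCKS:
            for _ in block:
                x = conv2d(x, self.convs[k], self.conv_biases[k], pad=1).relu()
                k += 1
            x = max_pool2d(x, 2)
        x = x.reshape(x.shape[0], -1)
        for fc in self.fcs[:-1]:
            x = fc(x).relu()
        return self.fcs[-1](x).relu()


# ----------------------------------------------------------------------- LSTM

class BiLSTM(Module):
    """One bi-directional LSTM layer; total output width = 2 * hidden."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W_f = Parameter(nn.fan_in_uniform(
            rng, (in_dim + hidden, 4 * hidden), fan_in=in_dim + hidden))
        self.b_f = Parameter(np.zeros(4 * hidden))
        self.W_b = Parameter(nn.fan_in_uniform(
            rng, (in_dim + hidden, 4 * hidden), fan_in=in_dim + hidden))
        self.b_b = Parameter(np.zeros(4 * hidden))

    def _run(self, xs, W, b):
        bsz = xs[0].shape[0]
        h = Tensor(np.zeros((bsz, self.hidden)))
        c = Tensor(np.zeros((bsz, self.hidden)))
        outs = []
        hd = self.hidden
        for x in xs:
            z = nn.concatenate([x, h], axis=-1) @ W + b
            i = z[:, :hd].sigmoid()
            f = z[:, hd:2 * hd].sigmoid()
            g = z[:, 2 * hd:3 * hd].tanh()
            o = z[:, 3 * hd:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, T, D) -> (B, T, 2*hidden)."""
        xs = [x[:, t, :] for t in range(x.shape[1])]
        fwd = self._run(xs, self.W_f, self.b_f)
        bwd = self._run(xs[::-1], self.W_b, self.b_b)[::-1]
        steps = [nn.concatenate([f, bw], axis=-1) for f, bw in zip(fwd, bwd)]
        return nn.stack(steps, axis=1)


class LSTMStack(Module):
    """Two bi-LSTM layers, 128 output units each (64 per direction)."""

    def __init__(self, in_dim: int, rng: np.random.Generator,
                 width: int = 128, n_layers: int = 2):
        half = width // 2
        self.layers = [BiLSTM(in_dim if i == 0 else width, half, rng)
                       for i in range(n_layers)]
        self.out_dim = width

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, T, D) -> (B, width): last fwd state + first bwd state."""
        for layer in self.layers:
            x = layer(x)
        half = self.layers[-1].hidden
        last_fwd = x[:, x.shape[1] - 1, :half]
        first_bwd = x[:, 0, half:]
        return nn.concatenate([last_fwd, first_bwd], axis=-1)


# ---------------------------------------------------------------- baselines

@dataclass(frozen=True)
class BaselineSpec:
    name: str  # cnn_lr | cnn_lstm | vit_lstm | vit_t
    image_size: int = 128
    backbone: str = "vgg16"  # or "small" for desk-scale runs
    vit_config: ViTConfig | None = None
    temporal_config: TemporalConfig | None = None
    n_combos: int = 51
    l2: float = 1e-3
    n_timestamps: int = 3
    seed: int = 0
    dropout: float = 0.25


class _ImageSeriesModel(YieldModel):
    """Shared plumbing: unsegmented image series + seed branch + head."""

    def __init__(self, spec: BaselineSpec):
        super().__init__()
        self.spec = spec
        self.input_size = spec.image_size

    def preprocess(self, records):
        images = self._stack_images(records)
        combo, y = self._labels(records)
        return {"images": images, "combo": combo, "y": y}

    def _encode_images(self, images, training, rng) -> Tensor:
        raise NotImplementedError

    def image_representation(self, data, idx, training=False, rng=None):
        images = np.asarray(data["images"][idx], dtype=np.float64)
        return self._encode_images(images, training, rng)


def _make_backbone(spec: BaselineSpec, rng) -> Module:
    if spec.backbone == "vgg16":
        return VGG16Backbone(spec.image_size, rng)
    if spec.backbone == "small":
        return ConvBackbone(spec.image_size, rng)
    raise ConfigurationError(f"unknown backbone: {spec.backbone}")


class CnnLrModel(_ImageSeriesModel):
    """CNN per timestamp; flattened features concatenated into a 256-unit
    L2-regularized linear-regression layer."""

    name = "cnn_lr"

    def __init__(self, spec: BaselineSpec):
        super().__init__(spec)
        rng = np.random.default_rng([spec.seed, 21])
        self.backbone = _make_backbone(spec, rng)
        self.lr_dense = Linear(
            spec.n_timestamps * self.backbone.out_dim, 256, rng)
        self.seed_encoder = SeedEncoder(spec.n_combos, rng,
                                        dropout=spec.dropout)
        self.head = Head(256 + 16, rng, dropout=spec.dropout)
        self.l2 = spec.l2

    def _encode_images(self, images, training, rng):
        b, t = images.shape[:2]
        feats = self.backbone(
            Tensor(images.reshape((b * t,) + images.shape[2:])))
        flat = feats.reshape(b, t * self.backbone.out_dim)
        return self.lr_dense(flat)  # linear activation: the LR module

    def l2_penalty(self):
        if self.l2 <= 0:
            return None
        return (self.lr_dense.W * self.lr_dense.W).sum() * self.l2


class CnnLstmModel(_ImageSeriesModel):
    name = "cnn_lstm"

    def __init__(self, spec: BaselineSpec):
        super().__init__(spec)
        rng = np.random.default_rng([spec.seed, 22])
        self.backbone = _make_backbone(spec, rng)
        self.lstm = LSTMStack(self.backbone.out_dim, rng)
        self.seed_encoder = SeedEncoder(spec.n_combos, rng,
                                        dropout=spec.dropout)
        self.head = Head(self.lstm.out_dim + 16, rng, dropout=spec.dropout)

    def _encode_images(self, images, training, rng):
        b, t = images.shape[:2]
        feats = self.backbone(
            Tensor(images.reshape((b * t,) + images.shape[2:])))
        return self.lstm(feats.reshape(b, t, self.backbone.out_dim))


class VitLstmModel(_ImageSeriesModel):
    name = "vit_lstm"

    def __init__(self, spec: BaselineSpec):
        super().__init__(spec)
        rng = np.random.default_rng([spec.seed, 23])
        self.vit = ViT(spec.vit_config or ViTConfig(image_size=spec.image_size),
                       rng)
        self.lstm = LSTMStack(self.vit.config.embed_dim, rng)
        self.seed_encoder = SeedEncoder(spec.n_combos, rng,
                                        dropout=spec.dropout)
        self.head = Head(self.lstm.out_dim + 16, rng, dropout=spec.dropout)

    def _encode_images(self, images, training, rng):
        b, t = images.shape[:2]
        feats = self.vit(images.reshape((b * t,) + images.shape[2:]),
                         training=training, rng=rng)
        return self.lstm(feats.reshape(b, t, self.vit.config.embed_dim))


class VitTModel(_ImageSeriesModel):
    """One ViT on the unsegmented image + the temporal transformer."""

    name = "vit_t"

    def __init__(self, spec: BaselineSpec):
        super().__init__(spec)
        rng = np.random.default_rng([spec.seed, 24])
        self.vit = ViT(spec.vit_config or ViTConfig(image_size=spec.image_size),
                       rng)
        d = self.vit.config.embed_dim
        self.temporal = TemporalEncoder(
            spec.temporal_config or TemporalConfig(embed_dim=d), rng)
        self.seed_encoder = SeedEncoder(spec.n_combos, rng,
                                        dropout=spec.dropout)
        self.head = Head(self.temporal.config.out_dim + 16, rng,
                         dropout=spec.dropout)

    def _encode_images(self, images, training, rng):
        b, t = images.shape[:2]
        feats = self.vit(images.reshape((b * t,) + images.shape[2:]),
                         training=training, rng=rng)
        d = self.vit.config.embed_dim
        return self.temporal(feats.reshape(b, t, d), training=training,
                             rng=rng)


_BASELINES = {
    "cnn_lr": CnnLrModel,
    "cnn_lstm": CnnLstmModel,
    "vit_lstm": VitLstmModel,
    "vit_t": VitTModel,
}


def build_baseline(spec: BaselineSpec) -> YieldModel:
    if spec.name not in _BASELINES:
        raise ConfigurationError(
            f"unknown baseline {spec.name!r}; choose from {sorted(_BASELINES)}")
    return _BASELINES[spec.name](spec)
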