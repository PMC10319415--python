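import numpy as np
import pytest

from vityield.attention_vit import ViTConfig
from vityield.errors import ConfigurationError, InvalidArgumentError
from vityield.nn import Tensor
from vityield.temporal_transformer import TemporalConfig, TemporalEncoder
from vityield.yield_models import (
    BaselineSpec, Head, ProposedModel, SeedEncoder,
    build_baseline, encode_seed, forward_proposed, fuse_features,
)

TINY_VIT = ViTConfig(image_size=32, patch_size=16, embed_dim=16, depth=1,
                     heads=2)
TINY_TEMP = TemporalConfig(embed_dim=16, depth=1, heads=2, out_dim=16)


def tiny_model(seed=0, use_seed_info=True):
    return ProposedModel(TINY_VIT, TINY_TEMP, n_combos=51, seed=seed,
                         use_seed_info=use_seed_info)


class TestSeedEncoder:
    def test_zero_weights_give_zero_vector(self, rng):
        enc = SeedEncoder(51, rng)
        for _, p in enc.named_parameters():
            p.data[:] = 0.0
        out = encode_seed(7, enc)
        assert out.shape == (16,)
        np.testing.assert_array_equal(out, 0.0)

    def test_output_length_16(self, rng):
        assert encode_seed(3, SeedEncoder(51, rng)).shape == (16,)

    def test_distinct_indices_distinct_outputs(self):
        for init in range(20):
            enc = SeedEncoder(51, np.random.default_rng(init))
            a, b = encode_seed(4, enc), encode_seed(40, enc)
            assert not np.allclose(a, b)

    def test_out_of_range_raises(self, rng):
        enc = SeedEncoder(51, rng)
        with pytest.raises(InvalidArgumentError):
            encode_seed(51, enc)
        with pytest.raises(InvalidArgumentError):
            encode_seed(-1, enc)

    def test_batch_matches_single(self, rng):
        enc = SeedEncoder(51, rng)
        batch = enc(np.array([3, 9])).numpy()
        np.testing.assert_allclose(batch[0], encode_seed(3, enc), atol=1e-12)
        np.testing.assert_allclose(batch[1], encode_seed(9, enc), atol=1e-12)


class TestFuseFeatures:
    def test_soil_ones_is_multiplicative_identity(self, rng):
        temporal = TemporalEncoder(TINY_TEMP, rng)
        head = Head(16 + 16, rng)
        fp = rng.normal(size=(3, 16))
        seed = rng.normal(size=16)
        a = fuse_features(fp, np.ones((3, 16)), seed, temporal, head).numpy()
        b = fuse_features(fp, fp * 0 + 1.0, seed, temporal, head).numpy()
        np.testing.assert_array_equal(a, b)
        # the fused series really is f_plant itself
        direct = head(
            __import__("vityield.nn", fromlist=["concatenate"]).concatenate(
                [temporal(Tensor(fp)), Tensor(seed)], axis=-1)).numpy()
        np.testing.assert_allclose(a, direct, atol=1e-12)

    def test_zero_plant_annihilates_image_branch(self, rng):
        temporal = TemporalEncoder(TINY_TEMP, rng)
        head = Head(32, rng)
        seed = rng.normal(size=16)
        soil1 = rng.normal(size=(3, 16))
        soil2 = rng.normal(size=(3, 16))
        a = fuse_features(np.zeros((3, 16)), soil1, seed, temporal, head)
        b = fuse_features(np.zeros((3, 16)), soil2, seed, temporal, head)
        np.testing.assert_allclose(a.numpy(), b.numpy(), atol=1e-12)

    def test_matches_compose_by_hand_oracle(self, rng):
        from vityield.nn import concatenate
        temporal = TemporalEncoder(TINY_TEMP, rng)
        head = Head(32, rng)
        fp = rng.normal(size=(3, 16))
        fs = rng.normal(size=(3, 16))
        seed = rng.normal(size=16)
        out = fuse_features(fp, fs, seed, temporal, head).numpy()
        v = temporal(Tensor(fp * fs))
        expected = head(concatenate([v, Tensor(seed)], axis=-1)).numpy()
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_misaligned_shapes_raise(self, rng):
        temporal = TemporalEncoder(TINY_TEMP, rng)
        head = Head(32, rng)
        with pytest.raises(InvalidArgumentError):
            fuse_features(np.zeros((3, 16)), np.zeros((2, 16)),
                          np.zeros(16), temporal, head)


class TestProposedModel:
    def test_forward_deterministic(self, small_dataset):
        model = tiny_model()
        rec = small_dataset.plots[0]
        assert forward_proposed(rec, model) == forward_proposed(rec, model)

    def test_forward_finite_on_synthetic_plots(self, small_dataset):
        model = tiny_model()
        for rec in small_dataset.plots[:5]:
            phi = forward_proposed(rec, model)
            assert np.isfinite(phi)

    def test_seed_index_counterfactual_changes_prediction(self, small_dataset):
        import copy
        model = tiny_model()
        rec = small_dataset.plots[0]
        base = forward_proposed(rec, model)
        other = copy.copy(rec)
        other.combo_index = (rec.combo_index + 5) % 51
        assert forward_proposed(other, model) != base

    def test_streams_do_not_share_weights(self):
        model = tiny_model()
        assert not np.array_equal(model.plant_vit.E.data, model.soil_vit.E.data)

    def test_without_seed_head_width(self):
        model = tiny_model(use_seed_info=False)
        assert model.seed_encoder is None
        assert model.head.fc1.W.shape[0] == TINY_TEMP.out_dim

    def test_seed_ablation_parameter_difference(self):
        with_seed = tiny_model(use_seed_info=True)
        without = tiny_model(use_seed_info=False)
        seed_params = (51 * 16 + 16) + 2 * (16 * 16 + 16)
        head_extra = 16 * 128  # fc1 input width shrinks by the 16 seed dims
        assert with_seed.n_parameters() - without.n_parameters() == \
            seed_params + head_extra

    def test_parameter_count_matches_shape_walking_oracle(self):
        model = tiny_model()
        c, t = TINY_VIT, TINY_TEMP
        d, dk, h, hid, n = (c.embed_dim, c.embed_dim // c.heads, c.heads,
                            c.hidden, c.n_patches)

        def block_params(width, heads, hidden):
            d_k = width // heads
            attn = heads * 3 * width * d_k + heads * d_k * width
            lns = 2 * (2 * width)
            mlp = width * hidden + hidden + hidden * width + width
            return attn + lns + mlp

        vit = (c.patch_size ** 2 * c.channels * d) + d + (n + 1) * d \
            + c.depth * block_params(d, h, hid) + 2 * d
        temporal = (d * d + d) + t.depth * block_params(d, t.heads, t.hidden) \
            + (d * t.out_dim + t.out_dim)
        seed = (51 * 16 + 16) + 2 * (16 * 16 + 16)
        head_in = t.out_dim + 16
        head = (head_in * 128 + 128) + 2 * (128 * 128 + 128) + (128 + 1)
        expected = 2 * vit + temporal + seed + head
        assert model.n_parameters() == expected


class TestBaselines:
    SPEC = dict(image_size=32, backbone="small", vit_config=TINY_VIT,
                temporal_config=TINY_TEMP, n_timestamps=3, seed=0)

    @pytest.mark.parametrize("name", ["cnn_lr", "cnn_lstm", "vit_lstm",
                                      "vit_t"])
    def test_each_baseline_finite_scalar(self, name, small_dataset):
        model = build_baseline(BaselineSpec(name=name, **self.SPEC))
        data = model.preprocess(small_dataset.plots[:3])
        out = model.forward_batch(data, np.arange(3)).numpy()
        assert out.shape == (3,)
        assert np.all(np.isfinite(out))

    def test_unknown_name_raises(self):
        with pytest.raises(ConfigurationError):
            build_baseline(BaselineSpec(name="resnet", **self.SPEC))

    def test_cnn_lr_l2_monotonicity(self, small_dataset):
        """Zero L2 reaches lower train MSE than a large penalty."""
        from vityield import train_eval
        records = small_dataset.plots[:10]
        losses = {}
        for l2 in (0.0, 50.0):
            model = build_baseline(BaselineSpec(name="cnn_lr", l2=l2,
                                                dropout=0.0, **self.SPEC))
            cfg = train_eval.TrainConfig(max_epochs=8, patience=8, seed=0,
                                         batch_size=5)
            train_eval.train(model, records, records, cfg)
            pred = model.predict(records)
            losses[l2] = np.mean((pred - [r.yield_kg_ha for r in records]) ** 2)
        assert losses[0.0] < losses[50.0]

    def test_vit_t_equals_fuse_with_unit_soil(self, small_dataset):
        """Structural equivalence: ViT-T == fusion pipeline with the soil
        stream frozen at the 1-vector and the plant stream on whole images."""
        model = build_baseline(BaselineSpec(name="vit_t", **self.SPEC))
        records = small_dataset.plots[:2]
        data = model.preprocess(records)
        out = model.forward_batch(data, np.arange(2)).numpy()

        images = data["images"].astype(np.float64)
        b, t = images.shape[:2]
        feats = model.vit(images.reshape((b * t,) + images.shape[2:]))
        fp = feats.numpy().reshape(b, t, -1)
        f_seed = model.seed_encoder(data["combo"][:2])
        expected = fuse_features(fp, np.ones_like(fp), f_seed,
                                 model.temporal, model.head).numpy()
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_vgg16_backbone_structure(self):
        from vityield.yield_models import VGG16Backbone
        backbone = VGG16Backbone(128, np.random.default_rng(0))
        assert len(backbone.convs) == 13  # 13 conv layers
        assert len(backbone.fcs) == 3     # 3 dense layers

    def test_vgg16_forward_smoke(self):
        from vityield.nn import Tensor
        from vityield.yield_models import VGG16Backbone
        backbone = VGG16Backbone(32, np.random.default_rng(0))
        out = backbone(Tensor(np.random.default_rng(1).random((1, 32, 32, 3))))
        assert out.shape == (1, 128)
        assert np.all(np.isfinite(out.numpy()))

    def test_shared_contract_predict(self, small_dataset):
        """Every model honours the same fit/predict surface."""
        records = small_dataset.plots[:4]
        models = [tiny_model()] + [
            build_baseline(BaselineSpec(name=n, **self.SPEC))
            for n in ("cnn_lr", "cnn_lstm", "vit_lstm", "vit_t")]
        for model in models:
            pred = model.predict(records)
            assert pred.shape == (4,)
            assert np.all(np.isfinite(pred))
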