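"""Architecture contracts for the residual-dense encoder and per-voxel MLP."""
import numpy as np
import pytest

from conftest import MICRO_DECODER, MICRO_ENCODER, TINY_DECODER, TINY_ENCODER
from fdosr.network import (
    DecoderConfig,
    EncoderConfig,
    FeatureField,
    SRModel,
    decode,
    encode,
    super_resolve,
)
from fdosr.volume import Volume3D


def _param_count_formula(enc: EncoderConfig, dec: DecoderConfig) -> int:
    """Closed-form parameter count, derived layer by layer by hand."""

    def conv(cin, cout, k):
        return cout * cin * k**3 + cout

    def lin(cin, cout):
        return cout * cin + cout

    total = conv(enc.in_channels, enc.base_channels, enc.conv_kernel)
    total += conv(enc.base_channels, enc.base_channels, enc.conv_kernel)
    for _ in range(enc.n_rdb):
        for l in range(enc.layers_per_rdb):
            total += conv(
                enc.base_channels + l * enc.growth_channels,
                enc.growth_channels,
                enc.conv_kernel,
            )
        total += conv(
            enc.base_channels + enc.layers_per_rdb * enc.growth_channels,
            enc.base_channels,
            enc.fusion_kernel,
        )
    total += conv(enc.n_rdb * enc.base_channels, enc.base_channels, enc.fusion_kernel)
    total += conv(enc.base_channels, enc.base_channels, enc.conv_kernel)
    total += conv(enc.base_channels, enc.feature_dim, enc.conv_kernel)
    widths = [enc.feature_dim] + [dec.hidden_width] * (dec.n_layers - 1) + [dec.output_dim]
    for i in range(dec.n_layers):
        total += lin(widths[i], widths[i + 1])
    return total


class TestArchitectureAudit:
    @pytest.mark.parametrize(
        "enc,dec",
        [
            (EncoderConfig(), DecoderConfig()),
            (TINY_ENCODER, TINY_DECODER),
            (MICRO_ENCODER, MICRO_DECODER),
        ],
    )
    def test_parameter_count_matches_closed_form(self, enc, dec):
        model = SRModel.initialize(enc, dec, seed=0)
        assert model.parameter_count() == _param_count_formula(enc, dec)

    def test_layer_inventory_matches_reference_architecture(self):
        """Default config: 8 RDBs x (3 conv+ReLU + 1 fusion), 2 shallow convs,
        2 global-fusion convs, 1 head conv to 128 channels, 8-layer decoder,
        no pooling/normalization/encoder-decoder skips."""
        model = SRModel.initialize(seed=0)
        inv = model.layer_inventory()
        roles = [l["role"] for l in inv]
        assert roles.count("shallow") == 2
        assert roles.count("rdb_layer") == 8 * 3
        assert roles.count("rdb_fusion") == 8
        assert roles.count("global_fusion") == 2
        assert roles.count("head") == 1
        assert roles.count("upscale") == 1
        assert roles.count("decoder") == 8
        head = next(l for l in inv if l["role"] == "head")
        assert head["out_ch"] == 128
        kinds = {l["kind"] for l in inv}
        assert kinds <= {"conv3d", "linear", "upscale"}
        assert not any("pool" in k or "norm" in k for k in kinds)
        # every RDB conv layer carries a ReLU; the decoder's last layer does not
        assert all(l.get("activation") == "relu" for l in inv if l["role"] == "rdb_layer")
        dec_layers = [l for l in inv if l["role"] == "decoder"]
        assert all(l["activation"] == "relu" for l in dec_layers[:-1])
        assert dec_layers[-1]["activation"] is None

    def test_dense_connectivity_widths(self):
        model = SRModel.initialize(TINY_ENCODER, TINY_DECODER, seed=0)
        for l in model.layer_inventory():
            if l["role"] == "rdb_layer":
                layer_idx = int(l["name"].split("layer")[1])
                expected = TINY_ENCODER.base_channels + layer_idx * TINY_ENCODER.growth_channels
                assert l["in_ch"] == expected
                assert model.params[l["name"] + "_w"].shape[1] == expected

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(n_rdb=0)
        with pytest.raises(ValueError):
            DecoderConfig(n_layers=1)
        with pytest.raises(ValueError):
            DecoderConfig(output_dim=2)


class TestEncode:
    def test_feature_field_shape_for_noninteger_factor(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((12, 12, 12)))
        f = encode(x, (30, 30, 30), model)
        assert f.data.shape == (MICRO_ENCODER.feature_dim, 30, 30, 30)

    def test_outputs_finite_and_deterministic(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=1)
        x = Volume3D(np.random.default_rng(1).random((10, 10, 10)))
        a = encode(x, (20, 20, 20), model)
        b = encode(x, (20, 20, 20), model)
        assert np.all(np.isfinite(a.data))
        np.testing.assert_array_equal(a.data, b.data)

    def test_refuses_to_downsample(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((12, 12, 12)))
        with pytest.raises(ValueError, match="super-resolve"):
            encode(x, (10, 12, 12), model)


class TestDecode:
    def test_shared_vector_gives_constant_output(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=2)
        v = np.random.default_rng(3).normal(size=MICRO_ENCODER.feature_dim)
        f = FeatureField(np.tile(v[:, None, None, None], (1, 4, 5, 6)).astype(np.float32))
        out = decode(f, model)
        assert out.shape == (4, 5, 6)
        assert np.ptp(out.data) < 1e-6

    def test_single_voxel_matches_standalone_affine_relu_chain(self):
        """The decoder equals an independently coded affine+ReLU chain."""
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=4)
        v = np.random.default_rng(5).normal(size=MICRO_ENCODER.feature_dim).astype(np.float32)
        f = FeatureField(v[:, None, None, None])
        out = decode(f, model)
        h = v.copy()
        for i in range(MICRO_DECODER.n_layers):
            w = model.params[f"mlp{i}_w"]
            b = model.params[f"mlp{i}_b"]
            h = w @ h + b
            if i < MICRO_DECODER.n_layers - 1:
                h = np.maximum(h, 0)
        assert out.data[0, 0, 0] == pytest.approx(float(h[0]), rel=1e-6)

    def test_zero_features_zero_biases_give_zero(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        for k in list(model.params):
            if k.startswith("mlp") and k.endswith("_b"):
                model.params[k] = np.zeros_like(model.params[k])
        f = FeatureField(np.zeros((MICRO_ENCODER.feature_dim, 3, 3, 3), dtype=np.float32))
        out = decode(f, model)
        np.testing.assert_array_equal(out.data, 0)

    def test_voxelwise_permutation_equivariance(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=6)
        rng = np.random.default_rng(7)
        f = rng.normal(size=(MICRO_ENCODER.feature_dim, 2, 3, 4)).astype(np.float32)
        out = decode(FeatureField(f), model).data
        perm = rng.permutation(2 * 3 * 4)
        f_perm = f.reshape(f.shape[0], -1)[:, perm].reshape(f.shape)
        out_perm = decode(FeatureField(f_perm), model).data
        np.testing.assert_allclose(out.reshape(-1)[perm], out_perm.reshape(-1), rtol=1e-6)

    def test_width_mismatch_raises(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        f = FeatureField(np.zeros((MICRO_ENCODER.feature_dim + 1, 2, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="width"):
            decode(f, model)


class TestSuperResolve:
    def test_rounding_rule_for_noninteger_factor(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((20, 20, 20)))
        assert super_resolve(x, 2.5, model).shape == (50, 50, 50)

    def test_identity_scale_keeps_dims(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((9, 9, 9)))
        assert super_resolve(x, 1.0, model).shape == (9, 9, 9)

    def test_untrained_model_smoke(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((8, 10, 12)))
        out = super_resolve(x, 3.0, model)
        assert out.shape == (24, 30, 36)
        assert np.all(np.isfinite(out.data))

    def test_subunit_scale_rejected(self):
        model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=0)
        x = Volume3D(np.random.default_rng(0).random((8, 8, 8)))
        with pytest.raises(ValueError):
            super_resolve(x, 0.9, model)


def test_checkpoint_round_trip(tmp_path):
    model = SRModel.initialize(MICRO_ENCODER, MICRO_DECODER, seed=11)
    path = tmp_path / "model.ckpt.npz"
    model.save(path)
    loaded = SRModel.load(path)
    assert loaded.encoder_cfg == model.encoder_cfg
    assert loaded.decoder_cfg == model.decoder_cfg
    for k, v in model.params.items():
        np.testing.assert_array_equal(loaded.params[k], v)
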