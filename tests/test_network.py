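"""Architecture contracts: residual identity and gradient pass-through,
decoder composition, shape contracts, sigmoid head, binarization."""

import numpy as np
import pytest

from lungseg.encoders import (
    EfficientNetB4Encoder,
    PretrainedWeightsUnavailableError,
    TinyEncoder,
)
from lungseg.network import (
    ConfigError,
    DecoderBlock,
    ModelConfig,
    ResidualBlock,
    UNet,
    assemble_model,
    leaky_relu,
    load_weights,
    predict_mask,
    relu,
    save_weights,
)
from lungseg.nn import autograd as ag
from lungseg.nn.autograd import Tensor

from conftest import finite_difference_grad


def tiny_config(size=64, **kw) -> ModelConfig:
    return ModelConfig(encoder="tiny_test", input_size=size, **kw)


class TestActivations:
    def test_leaky_relu_definition(self):
        assert leaky_relu(5.0) == 5.0
        assert leaky_relu(-1.0) == pytest.approx(-0.01)
        assert leaky_relu(-1.0, slope=0.2) == pytest.approx(-0.2)

    def test_relu_definition(self):
        assert relu(-1.0) == 0.0
        assert relu(2.5) == 2.5


class TestResidualBlock:
    def test_zero_branch_is_exact_identity(self):
        block = ResidualBlock(2, slope=0.01, rng=np.random.default_rng(0))
        block.zero_branch()
        x = np.random.default_rng(1).normal(size=(1, 2, 4, 4))
        for mode in (block.train(), block.eval()):
            out = mode(Tensor(x)).data
            assert np.array_equal(out, x)

    def test_shape_preserved(self):
        block = ResidualBlock(3, slope=0.01, rng=np.random.default_rng(0)).eval()
        out = block(Tensor(np.zeros((2, 3, 6, 5))))
        assert out.data.shape == (2, 3, 6, 5)

    def test_channel_mismatch_raises(self):
        block = ResidualBlock(3, slope=0.01, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="channels"):
            block(Tensor(np.zeros((1, 2, 4, 4))))

    def test_gradient_passthrough_matches_finite_differences(self):
        """dL/dx = upstream x (identity + branch Jacobian): the analytic
        gradient through x + C(B(x)) must match a central-difference oracle
        at step 1e-4 to relative error < 1e-3 on a 2x2x2 input."""
        block = ResidualBlock(2, slope=0.05, rng=np.random.default_rng(3)).eval()
        w = np.random.default_rng(4).normal(size=(1, 2, 2, 2))
        x0 = np.random.default_rng(5).normal(size=(1, 2, 2, 2))

        def loss(arr):
            return ag.sum_axes(ag.mul(block(Tensor(arr)), w))

        xt = Tensor(x0.copy(), requires_grad=True)
        loss_t = ag.sum_axes(ag.mul(block(xt), w))
        loss_t.backward()
        numeric = finite_difference_grad(lambda arr: loss(arr).item(), x0.copy(), h=1e-4)
        rel = np.abs(xt.grad - numeric).max() / max(np.abs(numeric).max(), 1e-12)
        assert rel < 1e-3

    def test_gradient_survives_zeroed_branch(self):
        """With the branch zeroed the input gradient equals the upstream
        gradient exactly — the shortcut transmits it unattenuated."""
        block = ResidualBlock(2, slope=0.01, rng=np.random.default_rng(0))
        block.zero_branch()
        block.eval()
        w = np.random.default_rng(1).normal(size=(1, 2, 3, 3))
        x = Tensor(np.random.default_rng(2).normal(size=(1, 2, 3, 3)), requires_grad=True)
        ag.sum_axes(ag.mul(block(x), w)).backward()
        np.testing.assert_array_equal(x.grad, w)


class TestDecoderBlock:
    def make(self, n_res, dropout=0.0):
        return DecoderBlock(
            in_channels=8,
            skip_channels=4,
            out_channels=6,
            n_residual=n_res,
            slope=0.01,
            dropout_rate=dropout,
            rng=np.random.default_rng(0),
        )

    @pytest.mark.parametrize("n_res", [0, 1, 2, 3])
    def test_residual_block_count(self, n_res):
        assert len(self.make(n_res).residual_blocks) == n_res

    def test_output_matches_skip_resolution(self):
        block = self.make(2).eval()
        out = block(Tensor(np.zeros((1, 8, 4, 4))), Tensor(np.zeros((1, 4, 8, 8))))
        assert out.data.shape == (1, 6, 8, 8)

    def test_skip_mismatch_raises(self):
        block = self.make(1)
        with pytest.raises(ValueError, match="skip"):
            block(Tensor(np.zeros((1, 8, 4, 4))), Tensor(np.zeros((1, 4, 6, 6))))

    def test_zero_dropout_is_deterministic_in_both_modes(self):
        block = self.make(2, dropout=0.0)
        x = Tensor(np.random.default_rng(0).normal(size=(1, 8, 4, 4)))
        skip = Tensor(np.random.default_rng(1).normal(size=(1, 4, 8, 8)))
        block.eval()
        a = block(x, skip).data
        b = block(x, skip).data
        assert np.array_equal(a, b)
        block.train()  # batch stats differ from running stats, but still no RNG
        c = block(x, skip).data
        d = block(x, skip).data
        assert np.array_equal(c, d)


class TestAssembledModel:
    def test_five_decoder_stages_two_residual_blocks_each(self):
        net = assemble_model(tiny_config())
        assert len(net.decoder_blocks) == 5
        assert all(len(b.residual_blocks) == 2 for b in net.decoder_blocks)

    def test_output_shape_single_channel_sigmoid(self):
        net = assemble_model(tiny_config(size=64)).eval()
        x = np.random.default_rng(0).random((2, 3, 64, 64))
        out = net(Tensor(x)).data
        assert out.shape == (2, 1, 64, 64)
        assert (out > 0).all() and (out < 1).all()

    @pytest.mark.parametrize("size", [32, 96])
    def test_shape_contract_for_any_multiple_of_32(self, size):
        net = assemble_model(tiny_config(size=size)).eval()
        out = net(Tensor(np.zeros((1, 3, size, size)))).data
        assert out.shape == (1, 1, size, size)

    def test_tiny_encoder_small_enough_for_cpu(self):
        assert assemble_model(tiny_config()).n_parameters() < 500_000

    def test_pretrained_encoder_raises_with_alternatives(self):
        with pytest.raises(PretrainedWeightsUnavailableError, match="tiny_test"):
            assemble_model(ModelConfig(encoder="efficientnet_b4_pretrained"))

    def test_efficientnet_b4_topology(self):
        enc = EfficientNetB4Encoder(rng=np.random.default_rng(0))
        assert enc.out_channels == (24, 32, 56, 160, 448)
        assert len(enc.stages) == 7
        # B4 depth scaling: 2, 4, 4, 6, 6, 8, 2 MBConv blocks per stage
        assert [len(s.layers) for s in enc.stages] == [2, 4, 4, 6, 6, 8, 2]
        feats = enc.eval()(Tensor(np.zeros((1, 3, 32, 32))))
        assert [f.data.shape[1:] for f in feats] == [
            (24, 16, 16), (32, 8, 8), (56, 4, 4), (160, 2, 2), (448, 1, 1),
        ]

    def test_tiny_encoder_pyramid(self):
        enc = TinyEncoder(rng=np.random.default_rng(0)).eval()
        feats = enc(Tensor(np.zeros((1, 3, 64, 64))))
        assert [f.data.shape[1] for f in feats] == [8, 16, 32, 64, 128]
        assert [f.data.shape[2] for f in feats] == [32, 16, 8, 4, 2]

    @pytest.mark.parametrize(
        "field,value",
        [
            ("input_size", 100),
            ("decoder_channels", (8, 8, 8)),
            ("residual_blocks_per_decoder", -1),
            ("dropout_rate", 1.0),
            ("activation", "gelu"),
            ("encoder", "resnet50"),
        ],
    )
    def test_config_validation(self, field, value):
        with pytest.raises(ConfigError):
            ModelConfig(**{"encoder": "tiny_test", field: value}).validate()


class TestPredictMask:
    @pytest.fixture()
    def net(self):
        return assemble_model(tiny_config(size=32), seed=1)

    def test_threshold_extremes(self, net):
        img = np.random.default_rng(0).random((32, 32, 3))
        assert predict_mask(net, img, threshold=0.0).all()
        assert not predict_mask(net, img, threshold=1.0).any()

    def test_wrong_resolution_names_expected_size(self, net):
        with pytest.raises(ValueError, match="32"):
            predict_mask(net, np.zeros((64, 64, 3)))

    def test_weight_roundtrip_preserves_predictions(self, net, tmp_path):
        img = np.random.default_rng(1).random((32, 32, 3))
        before = predict_mask(net, img)
        save_weights(net, tmp_path / "w.npz")
        other = assemble_model(tiny_config(size=32), seed=99)
        load_weights(other, tmp_path / "w.npz")
        assert np.array_equal(predict_mask(other, img), before)
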