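"""Block-level oracles (kernel-attention normalisation, convolution
linearity, pooling means, gate algebra) and whole-model contracts."""

import numpy as np
import pytest

import rdaunet._tensor as T
from rdaunet import network, nn
from rdaunet._tensor import Tensor
from rdaunet.network import ModelConfig


@pytest.fixture(autouse=True)
def _seed():
    nn.set_global_seed(77)


# ---------------------------------------------------------------------------
# dynamic convolution

def test_kernel_attention_rows_are_probability_vectors(rng):
    layer = nn.DynamicConv2d(4, 6, 3, K=3, padding=1)
    x = rng.normal(size=(2, 4, 8, 8)).astype(np.float32)
    pi = network.dyconv_attention(x, layer).data
    assert pi.shape == (2, 3)
    assert np.all(pi >= 0) and np.all(pi <= 1)
    assert np.allclose(pi.sum(axis=1), 1.0, atol=1e-6)


def test_zero_initialised_attention_is_uniform(rng):
    layer = nn.DynamicConv2d(4, 6, 3, K=5, padding=1)
    x = rng.normal(size=(3, 4, 6, 6)).astype(np.float32)
    assert np.allclose(network.dyconv_attention(x, layer).data, 0.2, atol=1e-7)


def test_attention_temperature_limits(rng):
    layer = nn.DynamicConv2d(2, 2, 3, K=4, padding=1)
    # give the attention MLP nonzero logits
    layer.att_fc2.weight.data = rng.normal(size=layer.att_fc2.weight.shape).astype(np.float32)
    x = rng.normal(size=(2, 2, 5, 5)).astype(np.float32)
    layer.temperature = 1e6
    assert np.allclose(network.dyconv_attention(x, layer).data, 0.25, atol=1e-4)
    layer.temperature = 1e-4
    hot = network.dyconv_attention(x, layer).data
    assert np.allclose(hot.max(axis=1), 1.0, atol=1e-4)


def test_dynamic_conv_K1_equals_static_conv(rng):
    layer = nn.DynamicConv2d(3, 5, 3, K=1, padding=1)
    x = rng.normal(size=(2, 3, 7, 7)).astype(np.float32)
    out = network.dynamic_conv(x, layer).data
    ref = T.conv2d(Tensor(x), Tensor(layer.weight.data[0]),
                   Tensor(layer.bias.data[0]), padding=1).data
    assert np.allclose(out, ref, atol=1e-6)


def test_dynamic_conv_one_hot_selects_kernel(rng):
    layer = nn.DynamicConv2d(2, 4, 3, K=3, padding=1)
    # bias the attention hard onto kernel 1 and make the softmax decisive
    layer.att_fc2.weight.data[:] = 0
    layer.att_fc2.bias.data[:] = np.array([-100, 100, -100], dtype=np.float32)
    layer.temperature = 1.0
    x = rng.normal(size=(1, 2, 6, 6)).astype(np.float32)
    out = network.dynamic_conv(x, layer).data
    ref = T.conv2d(Tensor(x), Tensor(layer.weight.data[1]),
                   Tensor(layer.bias.data[1]), padding=1).data
    assert np.allclose(out, ref, atol=1e-5)


def test_dynamic_conv_linearity_oracle(rng):
    """Aggregate-then-convolve == pi-weighted sum of per-kernel convolutions."""
    layer = nn.DynamicConv2d(2, 3, 3, K=3, padding=1)
    layer.att_fc2.weight.data = rng.normal(
        size=layer.att_fc2.weight.shape).astype(np.float32)
    layer.temperature = 1.0
    x = rng.normal(size=(1, 2, 6, 6)).astype(np.float32)
    pi = network.dyconv_attention(x, layer).data[0]
    out = network.dynamic_conv(x, layer).data
    ref = sum(pi[k] * T.conv2d(Tensor(x), Tensor(layer.weight.data[k]),
                               padding=1).data
              for k in range(3))
    ref = ref + (pi @ layer.bias.data).reshape(1, 3, 1, 1)
    assert np.allclose(out, ref, atol=1e-6)


def test_dynamic_conv_rejects_K0():
    with pytest.raises(ValueError, match="K >= 1"):
        nn.DynamicConv2d(2, 2, 3, K=0)


# ---------------------------------------------------------------------------
# res-double block / downsampling

def _identity_bn(bn):
    bn.training = False   # inference mode with fresh (0, 1) statistics


def test_res_block_zeroed_main_branch_is_relu_passthrough(rng):
    block = network.ResDoubleDyConv(4, 4, K=2)
    for m in block.modules():
        if isinstance(m, nn.BatchNorm2d):
            _identity_bn(m)
        if isinstance(m, nn.DynamicConv2d):
            m.weight.data[:] = 0
            m.bias.data[:] = 0
    x = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
    out = network.res_double_dyconv(x, block).data
    assert np.allclose(out, np.maximum(x, 0), atol=1e-6)


def test_res_block_shape_contract(rng):
    block = network.ResDoubleDyConv(8, 16, K=2)
    block.eval()
    x = rng.normal(size=(1, 8, 32, 32)).astype(np.float32)
    assert network.res_double_dyconv(x, block).shape == (1, 16, 32, 32)


def test_res_block_gradient_matches_finite_differences(rng):
    block = network.ResDoubleDyConv(2, 2, K=2)
    block.eval()
    for p in block.parameters():
        p.data = p.data.astype(np.float64)
    x = Tensor(rng.normal(size=(1, 2, 5, 5)))
    x.requires_grad = True

    def fn():
        return T.tsum(block(x) ** 2.0)

    fn().backward()
    eps = 1e-6
    idx = (0, 1, 2, 3)
    orig = x.data[idx]
    x.data[idx] = orig + eps
    lp = float(fn().data)
    x.data[idx] = orig - eps
    lm = float(fn().data)
    x.data[idx] = orig
    num = (lp - lm) / (2 * eps)
    assert num == pytest.approx(x.grad[idx], rel=1e-4, abs=1e-8)


@pytest.mark.parametrize("hw,expected", [(64, 32), (65, 33)])
def test_strided_downsample_ceil_convention(rng, hw, expected):
    down = network.StridedDownsample(4, 8)
    x = rng.normal(size=(1, 4, hw, hw)).astype(np.float32)
    out = network.strided_downsample(x, down)
    assert out.shape == (1, 8, expected, expected)


# ---------------------------------------------------------------------------
# coordinate attention

def test_ca_pooling_matches_brute_force_axis_means(rng):
    ca = network.CoordinateAttention(4, reduction=2)
    x = rng.normal(size=(3, 4, 5, 6)).astype(np.float64)
    zh, zw = ca.pool(Tensor(x))
    for b in range(3):
        for c in range(4):
            for h in range(5):
                assert zh.data[b, c, h, 0] == pytest.approx(
                    sum(x[b, c, h, i] for i in range(6)) / 6)
            for w in range(6):
                assert zw.data[b, c, 0, w] == pytest.approx(
                    sum(x[b, c, j, w] for j in range(5)) / 5)


def test_ca_constant_row_pools_to_constant():
    x = np.zeros((1, 1, 3, 4), dtype=np.float32)
    x[0, 0, 1, :] = 2.5
    ca = network.CoordinateAttention(1, reduction=1)
    zh, _ = ca.pool(Tensor(x))
    assert zh.data[0, 0, 1, 0] == pytest.approx(2.5)


def test_ca_singleton_spatial_pooling(rng):
    x = rng.normal(size=(2, 3, 1, 1)).astype(np.float32)
    ca = network.CoordinateAttention(3)
    zh, zw = ca.pool(Tensor(x))
    assert np.allclose(zh.data, x) and np.allclose(zw.data, x)


def test_ca_output_is_bounded_modulation(rng):
    ca = network.CoordinateAttention(4, reduction=2)
    x = np.abs(rng.normal(size=(2, 4, 6, 6))).astype(np.float32)
    out = network.coordinate_attention(x, ca).data
    assert out.shape == x.shape
    assert np.all(np.abs(out) <= np.abs(x) + 1e-7)


def test_ca_reduction_floors_at_one_channel():
    ca = network.CoordinateAttention(4, reduction=100)
    assert ca.squeeze.weight.shape[0] == 1
    with pytest.raises(ValueError):
        network.CoordinateAttention(4, reduction=0)


# ---------------------------------------------------------------------------
# attention gate

def test_ag_zeroed_transforms_give_half_gain(rng):
    ag = network.AttentionGate(4, 8)
    for p in ag.parameters():
        p.data[:] = 0
    xl = rng.normal(size=(1, 4, 16, 16)).astype(np.float32)
    g = rng.normal(size=(1, 8, 8, 8)).astype(np.float32)
    out = network.attention_gate(xl, g, ag).data
    assert np.allclose(out, 0.5 * xl, atol=1e-6)


def test_ag_shape_contract_and_open_interval(rng):
    ag = network.AttentionGate(32, 64)
    xl = rng.normal(size=(1, 32, 64, 64)).astype(np.float32)
    g = rng.normal(size=(1, 64, 32, 32)).astype(np.float32)
    out = network.attention_gate(xl, g, ag)
    assert out.shape == (1, 32, 64, 64)
    alpha = ag.coefficients(Tensor(xl), Tensor(g)).data
    assert np.all(alpha > 0) and np.all(alpha < 1)


# ---------------------------------------------------------------------------
# decoder fusion

def test_fusion_single_level_is_degenerate(rng):
    fusion = network.DecoderFusion([8], head_ch=4)
    x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)
    out = network.decoder_multiscale_fusion([x], fusion)
    assert out.shape == (1, 4, 16, 16)


def test_fusion_resolution_contract(rng):
    fusion = network.DecoderFusion([16, 8, 4], head_ch=4)
    levels = [rng.normal(size=(1, c, s, s)).astype(np.float32)
              for c, s in ((16, 16), (8, 32), (4, 64))]
    out = network.decoder_multiscale_fusion(levels, fusion)
    assert out.shape == (1, 4, 64, 64)


def test_fusion_empty_list_raises():
    fusion = network.DecoderFusion([4], head_ch=4)
    with pytest.raises(ValueError):
        fusion([])


# ---------------------------------------------------------------------------
# whole models

@pytest.mark.parametrize("variant", network.VARIANTS)
def test_every_variant_maps_hw_to_hw_probability(rng, variant):
    cfg = ModelConfig(variant=variant, base_channels=4, depth=2, K=2)
    model = network.build_model(cfg).eval()
    x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
    out = network.forward(model, x)
    assert out.shape == (1, 1, 32, 32)
    assert np.all(out.data > 0) and np.all(out.data < 1)


def test_variant_module_census():
    mk = lambda v: network.summarize(network.build_model(
        ModelConfig(variant=v, base_channels=4, depth=2, K=2)))
    full = mk("rdau")
    assert full["n_coordinate_attention"] == 2
    assert full["n_attention_gates"] == 2
    assert full["has_decoder_fusion"]
    wa = mk("rdau_wA")
    assert wa["n_coordinate_attention"] == 0 and wa["n_attention_gates"] == 0
    wd = mk("rdau_wD")
    assert wd["n_dynamic_conv"] == 0
    wc = mk("rdau_wC")
    assert not wc["has_decoder_fusion"]
    un = mk("unet")
    assert un["n_dynamic_conv"] == 0 and un["n_coordinate_attention"] == 0


def test_removing_attention_removes_parameters():
    n = lambda v: network.build_model(
        ModelConfig(variant=v, base_channels=4, depth=2, K=2)).n_parameters()
    assert n("rdau_wA") < n("rdau")


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="variant"):
        ModelConfig(variant="resnet")


def test_constant_input_gives_constant_output(rng):
    model = network.build_model(ModelConfig(base_channels=4, depth=2, K=2)).eval()
    out = network.forward(model, np.zeros((1, 1, 32, 32), np.float32)).data
    assert np.ptp(out) < 1e-6


def test_inference_is_deterministic(rng):
    model = network.build_model(ModelConfig(base_channels=4, depth=2, K=2)).eval()
    x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
    a = network.forward(model, x).data
    b = network.forward(model, x).data
    assert np.array_equal(a, b)


def test_indivisible_input_raises_with_padding_hint(rng):
    model = network.build_model(ModelConfig(base_channels=4, depth=2, K=2)).eval()
    with pytest.raises(ValueError, match="pad"):
        network.forward(model, rng.normal(size=(1, 1, 30, 30)).astype(np.float32))


def test_checkpoint_round_trip_bitwise(tmp_path, rng):
    model = network.build_model(ModelConfig(base_channels=4, depth=2, K=2))
    x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
    model.train()
    model(Tensor(x))          # move BN running stats off their init values
    model.eval()
    ref = network.forward(model, x).data
    path = tmp_path / "model.npz"
    network.save_model(model, path)
    clone = network.load_model(path).eval()
    assert np.array_equal(network.forward(clone, x).data, ref)
    assert clone.config == model.config
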