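"""Res-double dynamic-conv attention U-Net for organoid segmentation.

The model is an encoder--decoder with skip connections.  Relative to a
vanilla U-Net it makes four changes:

* every double-convolution block is a *res-double dynamic convolution*:
  BN -> ReLU -> DyConv(dilation 1) -> BN -> ReLU -> DyConv(dilation 2) -> BN,
  added to a residual projection of the input and passed through a final
  ReLU.  The two dilation rates {1, 2} enlarge the receptive field; the
  residual path stabilises deep training.
* max pooling is replaced by a 5x5 stride-2 convolution that doubles the
  channel count, so downsampling itself is learned.
* coordinate attention (CA) refines the last two encoder levels: the map is
  average-pooled separately along height and width, squeezed through a
  shared bottleneck convolution, and expanded into per-row and per-column
  sigmoid gates g^h(i), g^w(j) that multiply the input elementwise.
* every skip connection passes through an attention gate (AG) driven by the
  coarser decoder feature, and the decoder head fuses all decoder levels
  (convolve each, upsample to the finest resolution, concatenate, reduce).

Ablation variants remove exactly one ingredient: ``rdau_wA`` the attention
modules (CA + AG), ``rdau_wD`` the res-double dynamic convolutions (plain
double conv instead), ``rdau_wC`` the multi-scale decoder fusion.  ``unet``
is the classic max-pool / double-conv baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import _tensor as T
from ._tensor import Tensor
from . import nn

__all__ = [
    "ModelConfig", "build_model", "forward", "RDAUNet", "UNet",
    "ResDoubleDyConv", "PlainDoubleConv", "StridedDownsample",
    "CoordinateAttention", "AttentionGate", "DecoderFusion",
    "dyconv_attention", "dynamic_conv", "res_double_dyconv",
    "strided_downsample", "coordinate_attention", "attention_gate",
    "decoder_multiscale_fusion", "save_model", "load_model", "summarize",
]

VARIANTS = ("unet", "rdau", "rdau_wA", "rdau_wC", "rdau_wD")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``depth`` counts downsamplings, so the encoder has ``depth + 1`` levels;
    channel width doubles at each downsampling starting from
    ``base_channels``.  ``K`` is the number of parallel kernels per dynamic
    convolution and ``temperature`` the initial softness of the kernel
    attention.  CA is placed on the last two encoder levels with bottleneck
    reduction ``ca_reduction`` (floored at one channel).
    """

    variant: str = "rdau"
    in_channels: int = 1
    base_channels: int = 32
    depth: int = 4
    K: int = 4
    ca_reduction: int = 16
    temperature: float = 30.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


# ---------------------------------------------------------------------------
# blocks

class ResDoubleDyConv(nn.Module):
    """BN/ReLU/DyConv(d=1)/BN/ReLU/DyConv(d=2)/BN + residual, final ReLU."""

    def __init__(self, in_ch: int, out_ch: int, *, K: int = 4,
                 temperature: float = 30.0, rng=None):
        super().__init__()
        self.bn1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.DynamicConv2d(in_ch, out_ch, 3, K=K, padding=1,
                                      dilation=1, temperature=temperature, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.DynamicConv2d(out_ch, out_ch, 3, K=K, padding=2,
                                      dilation=2, temperature=temperature, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.proj = (None if in_ch == out_ch
                     else nn.Conv2d(in_ch, out_ch, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(T.relu(self.bn1(x)))
        h = self.conv2(T.relu(self.bn2(h)))
        h = self.bn3(h)
        res = x if self.proj is None else self.proj(x)
        return T.relu(h + res)


class PlainDoubleConv(nn.Module):
    """Classic U-Net double convolution: (Conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, in_ch: int, out_ch: int, *, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        h = T.relu(self.bn1(self.conv1(x)))
        return T.relu(self.bn2(self.conv2(h)))


class StridedDownsample(nn.Module):
    """5x5 stride-2 convolution (padding 2): H -> ceil(H/2), learned pooling."""

    def __init__(self, in_ch: int, out_ch: int, *, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 5, stride=2, padding=2, rng=rng)
        self.bn = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError("input too small to downsample")
        return T.relu(self.bn(self.conv(x)))


class CoordinateAttention(nn.Module):
    """Factorised spatial attention.

    Height pooling z^h(c, i) = mean_j x(c, i, j) and width pooling
    z^w(c, j) = mean_i x(c, i, j) are concatenated along the spatial axis,
    squeezed by a shared 1x1 convolution (channels / r, floored at 1) with
    ReLU, split back, expanded by per-direction 1x1 convolutions and gated
    with sigmoids; the output is x * g^h(i) * g^w(j).
    """

    def __init__(self, channels: int, *, reduction: int = 16, rng=None):
        super().__init__()
        if reduction < 1:
            raise ValueError("reduction ratio must be >= 1")
        mid = max(channels // reduction, 1)
        self.squeeze = nn.Conv2d(channels, mid, 1, rng=rng)
        self.expand_h = nn.Conv2d(mid, channels, 1, rng=rng)
        self.expand_w = nn.Conv2d(mid, channels, 1, rng=rng)

    def pool(self, x: Tensor) -> tuple[Tensor, Tensor]:
        zh = T.tmean(x, axis=3, keepdims=True)            # (B, C, H, 1)
        zw = T.tmean(x, axis=2, keepdims=True)            # (B, C, 1, W)
        return zh, zw

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        zh, zw = self.pool(x)
        zw_t = T.transpose(zw, (0, 1, 3, 2))              # (B, C, W, 1)
        f = T.relu(self.squeeze(T.concat([zh, zw_t], axis=2)))
        fh = T.slice_axis(f, 2, 0, H)                     # (B, mid, H, 1)
        fw = T.transpose(T.slice_axis(f, 2, H, H + W), (0, 1, 3, 2))
        gh = T.sigmoid(self.expand_h(fh))                 # (B, C, H, 1)
        gw = T.sigmoid(self.expand_w(fw))                 # (B, C, 1, W)
        return x * gh * gw


class AttentionGate(nn.Module):
    """Skip-connection gate: alpha = sigma(psi(ReLU(Wx x^l + Wg g))).

    The skip feature x^l is brought to the gating signal's (coarser)
    resolution by a stride-2 1x1 convolution; the coefficient map is
    restored to x^l's size by bilinear resampling and multiplies x^l.
    """

    def __init__(self, x_ch: int, g_ch: int, inter_ch: int | None = None, *, rng=None):
        super().__init__()
        inter_ch = inter_ch or max(x_ch // 2, 1)
        self.wx = nn.Conv2d(x_ch, inter_ch, 1, stride=2, bias=False, rng=rng)
        self.wg = nn.Conv2d(g_ch, inter_ch, 1, rng=rng)
        self.psi = nn.Conv2d(inter_ch, 1, 1, rng=rng)

    def coefficients(self, xl: Tensor, g: Tensor) -> Tensor:
        fused = T.relu(self.wx(xl) + self.wg(g))
        alpha = T.sigmoid(self.psi(fused))                # (B, 1, H/2, W/2)
        return T.upsample2x_bilinear(alpha)

    def forward(self, xl: Tensor, g: Tensor) -> Tensor:
        return xl * self.coefficients(xl, g)


class DecoderFusion(nn.Module):
    """Convolve each decoder output, upsample all to the finest resolution,
    concatenate along channels and reduce to ``head_ch``."""

    def __init__(self, level_channels: list[int], head_ch: int, *, rng=None):
        super().__init__()
        self.convs = [nn.Conv2d(c, head_ch, 3, padding=1, rng=rng)
                      for c in level_channels]
        self.reduce = nn.Conv2d(head_ch * len(level_channels), head_ch, 1, rng=rng)

    def forward(self, decoder_outputs: list[Tensor]) -> Tensor:
        if not decoder_outputs:
            raise ValueError("decoder fusion needs at least one level")
        finest_hw = decoder_outputs[-1].shape[2:]
        lifted = []
        for conv, level in zip(self.convs, decoder_outputs):
            h = T.relu(conv(level))
            while h.shape[2] < finest_hw[0]:
                h = T.upsample2x_bilinear(h)
            lifted.append(h)
        if len(lifted) == 1:
            return lifted[0]
        cat = T.concat(lifted, axis=1)
        assert cat.shape[1] == sum(l.shape[1] for l in lifted)
        return T.relu(self.reduce(cat))


# ---------------------------------------------------------------------------
# models

class RDAUNet(nn.Module):
    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng or nn.get_rng()
        c = [config.base_channels * 2 ** i for i in range(config.depth + 1)]
        dyn = config.variant != "rdau_wD"
        attn = config.variant != "rdau_wA"
        self.use_fusion = config.variant != "rdau_wC"

        def block(i, o):
            if dyn:
                return ResDoubleDyConv(i, o, K=config.K,
                                       temperature=config.temperature, rng=rng)
            return PlainDoubleConv(i, o, rng=rng)

        self.enc_blocks = [block(config.in_channels if i == 0 else c[i], c[i])
                           for i in range(config.depth + 1)]
        self.downs = [StridedDownsample(c[i], c[i + 1], rng=rng)
                      for i in range(config.depth)]
        # CA on the last two encoder levels
        self.ca = ([CoordinateAttention(c[-2], reduction=config.ca_reduction, rng=rng),
                    CoordinateAttention(c[-1], reduction=config.ca_reduction, rng=rng)]
                   if attn else [])
        self.ups = [nn.ConvTranspose2x(c[i + 1], c[i], rng=rng)
                    for i in range(config.depth)]
        self.gates = ([AttentionGate(c[i], c[i + 1], rng=rng)
                       for i in range(config.depth)] if attn else [])
        self.dec_blocks = [block(2 * c[i], c[i]) for i in range(config.depth)]
        if self.use_fusion:
            self.fusion = DecoderFusion(c[config.depth - 1::-1],
                                        config.base_channels, rng=rng)
            self.head = nn.Conv2d(config.base_channels, 1, 1, rng=rng)
        else:
            self.head = nn.Conv2d(c[0], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        H, W = x.shape[2], x.shape[3]
        div = 2 ** cfg.depth
        if H % div or W % div:
            raise ValueError(
                f"spatial dims {H}x{W} not divisible by 2^depth={div}; "
                "pad the input to a multiple (see imaging_io tiling)")
        skips = []
        h = x
        for i in range(cfg.depth):
            h = self.enc_blocks[i](h)
            if self.ca and i == cfg.depth - 1:
                h = self.ca[0](h)
            skips.append(h)
            h = self.downs[i](h)
        h = self.enc_blocks[cfg.depth](h)
        if self.ca:
            h = self.ca[1](h)
        decoder_outputs = []
        for i in range(cfg.depth - 1, -1, -1):
            skip = self.gates[i](skips[i], h) if self.gates else skips[i]
            up = self.ups[i](h)
            h = self.dec_blocks[i](T.concat([up, skip], axis=1))
            decoder_outputs.append(h)
        feat = self.fusion(decoder_outputs) if self.use_fusion else decoder_outputs[-1]
        return T.sigmoid(self.head(feat))


class UNet(nn.Module):
    """Vanilla U-Net baseline: double conv, max pooling, plain skips."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng or nn.get_rng()
        c = [config.base_channels * 2 ** i for i in range(config.depth + 1)]
        self.enc_blocks = [PlainDoubleConv(config.in_channels if i == 0 else c[i - 1],
                                           c[i], rng=rng)
                           for i in range(config.depth + 1)]
        self.ups = [nn.ConvTranspose2x(c[i + 1], c[i], rng=rng)
                    for i in range(config.depth)]
        self.dec_blocks = [PlainDoubleConv(2 * c[i], c[i], rng=rng)
                           for i in range(config.depth)]
        self.head = nn.Conv2d(c[0], 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        div = 2 ** cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"spatial dims not divisible by 2^depth={div}; pad the input")
        skips = []
        h = x
        for i in range(cfg.depth):
            h = self.enc_blocks[i](h)
            skips.append(h)
            h = T.maxpool2x(h)
        h = self.enc_blocks[cfg.depth](h)
        for i in range(cfg.depth - 1, -1, -1):
            h = self.dec_blocks[i](T.concat([self.ups[i](h), skips[i]], axis=1))
        return T.sigmoid(self.head(h))


def build_model(config: ModelConfig, rng=None) -> nn.Module:
    """Instantiate the configured variant (seeded via ``rng`` or the global RNG)."""
    if config.variant == "unet":
        return UNet(config, rng=rng)
    return RDAUNet(config, rng=rng)


def forward(model: nn.Module, batch) -> Tensor:
    """Run a batch (array or Tensor, NCHW) through the model in its current mode."""
    x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, dtype=np.float32))
    return model(x)


# ---------------------------------------------------------------------------
# functional aliases matching the operation-level contracts

def dyconv_attention(x, layer: nn.DynamicConv2d) -> Tensor:
    """Kernel-attention distribution pi(x): rows are probability vectors."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return layer.attention(x)


def dynamic_conv(x, layer: nn.DynamicConv2d) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    return layer(x)


def res_double_dyconv(x, block: ResDoubleDyConv) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    return block(x)


def strided_downsample(x, layer: StridedDownsample) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    return layer(x)


def coordinate_attention(x, module: CoordinateAttention) -> Tensor:
    x = x if isinstance(x, Tensor) else Tensor(x)
    return module(x)


def attention_gate(xl, g, module: AttentionGate) -> Tensor:
    xl = xl if isinstance(xl, Tensor) else Tensor(xl)
    g = g if isinstance(g, Tensor) else Tensor(g)
    return module(xl, g)


def decoder_multiscale_fusion(decoder_outputs: list, module: DecoderFusion) -> Tensor:
    outs = [o if isinstance(o, Tensor) else Tensor(o) for o in decoder_outputs]
    return module(outs)


# ---------------------------------------------------------------------------
# persistence / introspection

def save_model(model: nn.Module, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_model(path) -> nn.Module:
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    cfg = ModelConfig(**json.loads(bytes(state.pop("__config__")).decode()))
    model = build_model(cfg)
    model.load_state_dict(state)
    return model


def summarize(model: nn.Module) -> dict:
    """Architecture summary (JSON-serialisable) for introspection."""
    mods = list(model.modules())
    return {
        "variant": model.config.variant,
        "n_parameters": model.n_parameters(),
        "n_dynamic_conv": sum(isinstance(m, nn.DynamicConv2d) for m in mods),
        "n_coordinate_attention": sum(isinstance(m, CoordinateAttention) for m in mods),
        "n_attention_gates": sum(isinstance(m, AttentionGate) for m in mods),
        "has_decoder_fusion": any(isinstance(m, DecoderFusion) for m in mods),
        "config": asdict(model.config),
    }
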