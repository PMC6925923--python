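"""Generator and discriminator architectures as declarative layer graphs.

The translation generator follows the encoder/convertor/decoder recipe:
``c7s1-64, d128, d256, 6 x R256, u64, u32, c7s1-out`` — a 7x7 stride-1 conv,
two stride-2 downsampling convs, six residual blocks at 4x width, two
fractional-stride (transposed) upsampling convs at widths 64 and 32, and a
final 7x7 projection.  Note the deliberately asymmetric decoder widths
(u64/u32 against a width-64 encoder).  The discriminator is a fully
convolutional patch critic: C64-C128-C256-C512 (4x4, stride 2, instance
norm on every block, LeakyReLU slope 0.2) followed by a 4x4 stride-1 conv
with a single filter, emitting a 2-D map of per-patch realness scores.

Each architecture exists twice: as a list of :class:`LayerDesc` records
(inspectable, closed-form parameter counting) and as a realized
:class:`~cyclect.nn.Network` built from the same list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

#: default init std for conv kernels (CycleGAN convention)
INIT_STD = 0.02


@dataclass(frozen=True)
class LayerDesc:
    kind: str                  # conv | conv_transpose | res_block
    kernel: int
    stride: int
    in_channels: int
    filters: int
    norm: bool = True
    activation: str = "relu"   # relu | leaky_relu | none
    padding: int = 0
    padding_mode: str = "zero"  # zero | reflect


@dataclass
class GeneratorSpec:
    in_channels: int
    out_channels: int
    width: int
    n_res_blocks: int
    layer_list: list[LayerDesc] = field(default_factory=list)


@dataclass
class DiscriminatorSpec:
    in_channels: int
    width: int
    layer_list: list[LayerDesc] = field(default_factory=list)


def build_generator(in_channels: int = 1, out_channels: int = 1,
                    width: int = 64, n_res_blocks: int = 6) -> GeneratorSpec:
    """Declarative generator spec; realize with :func:`realize_generator`."""
    if width < 1 or n_res_blocks < 0 or in_channels < 1 or out_channels < 1:
        raise ValueError("invalid generator configuration")
    w = width
    dec1, dec2 = w, max(w // 2, 1)
    layers = [
        LayerDesc("conv", 7, 1, in_channels, w, True, "relu", 3, "reflect"),
        LayerDesc("conv", 3, 2, w, 2 * w, True, "relu", 1),
        LayerDesc("conv", 3, 2, 2 * w, 4 * w, True, "relu", 1),
    ]
    layers += [LayerDesc("res_block", 3, 1, 4 * w, 4 * w, True, "relu", 1)
               for _ in range(n_res_blocks)]
    layers += [
        LayerDesc("conv_transpose", 3, 2, 4 * w, dec1, True, "relu", 1),
        LayerDesc("conv_transpose", 3, 2, dec1, dec2, True, "relu", 1),
        # final projection: linear output, intensity scaling handled by the
        # data pipeline
        LayerDesc("conv", 7, 1, dec2, out_channels, False, "none", 3, "reflect"),
    ]
    return GeneratorSpec(in_channels, out_channels, width, n_res_blocks, layers)


def build_discriminator(in_channels: int = 1, width: int = 64) -> DiscriminatorSpec:
    """Declarative patch-critic spec; realize with :func:`realize_discriminator`."""
    if width < 1 or in_channels < 1:
        raise ValueError("invalid discriminator configuration")
    w = width
    chans = [in_channels, w, 2 * w, 4 * w, 8 * w]
    layers = [LayerDesc("conv", 4, 2, chans[i], chans[i + 1], True, "leaky_relu", 1)
              for i in range(4)]
    layers.append(LayerDesc("conv", 4, 1, 8 * w, 1, False, "none", 1))
    return DiscriminatorSpec(in_channels, width, layers)


def _activation(name: str) -> nn.Layer | None:
    if name == "relu":
        return nn.ReLU()
    if name == "leaky_relu":
        return nn.LeakyReLU(0.2)
    if name == "none":
        return None
    raise ValueError(f"unknown activation {name!r}")


def _realize_block(d: LayerDesc, name: str) -> list[nn.Layer]:
    out: list[nn.Layer] = []
    if d.kind == "conv":
        pad = d.padding
        if d.padding_mode == "reflect" and pad:
            out.append(nn.ReflectionPad2d(pad))
            pad = 0
        out.append(nn.Conv2d(d.in_channels, d.filters, d.kernel, d.stride, pad, name=name))
    elif d.kind == "conv_transpose":
        out.append(nn.ConvTranspose2d(d.in_channels, d.filters, d.kernel, d.stride,
                                      d.padding, output_pad=1, name=name))
    elif d.kind == "res_block":
        body = [nn.Conv2d(d.in_channels, d.filters, 3, 1, 1, name=f"{name}.conv1"),
                nn.InstanceNorm2d(), nn.ReLU(),
                nn.Conv2d(d.filters, d.filters, 3, 1, 1, name=f"{name}.conv2"),
                nn.InstanceNorm2d()]
        return [nn.Residual(nn.Sequential(body))]
    else:
        raise ValueError(f"unknown layer kind {d.kind!r}")
    if d.norm:
        out.append(nn.InstanceNorm2d())
    act = _activation(d.activation)
    if act is not None:
        out.append(act)
    return out


def _realize(layer_list: list[LayerDesc], prefix: str) -> nn.Network:
    layers: list[nn.Layer] = []
    for i, d in enumerate(layer_list):
        layers.extend(_realize_block(d, f"{prefix}.{i}"))
    return nn.Network(nn.Sequential(layers))


def realize_generator(spec: GeneratorSpec) -> nn.Network:
    return _realize(spec.layer_list, "G")


def realize_discriminator(spec: DiscriminatorSpec) -> nn.Network:
    return _realize(spec.layer_list, "D")


def count_parameters(spec: GeneratorSpec | DiscriminatorSpec) -> int:
    """Exact learnable-parameter count from layer arithmetic alone.

    Convolutions carry k*k*cin*cout weights + cout biases; a residual block
    holds two such 3x3 convolutions; instance norm is parameter-free.
    Independent of any realized network and of input size.
    """
    total = 0
    for d in spec.layer_list:
        if d.kind == "res_block":
            total += 2 * (3 * 3 * d.in_channels * d.filters + d.filters)
        else:
            total += d.kernel * d.kernel * d.in_channels * d.filters + d.filters
    return total


def initialize_weights(net: nn.Network, seed: int, std: float = INIT_STD
                       ) -> dict[str, np.ndarray]:
    """Seeded N(0, std) kernel / zero bias init; returns the weight state."""
    net.init_weights(seed, std=std)
    return net.get_weights()


def discriminator_score_map_size(spec: DiscriminatorSpec, side: int) -> int:
    """Closed-form output side for a square input of the given side."""
    s = side
    for d in spec.layer_list:
        s = (s + 2 * d.padding - d.kernel) // d.stride + 1
    return s
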