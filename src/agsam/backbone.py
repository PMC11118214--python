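"""The trainable agent segmentation network: encoder and decoder.

Three encoder variants share one shape contract -- input ``[N, 3, S, S]``,
output ``[N, agent_dim, S/8, S/8]``:

* ``fcn``    : ResNet-50-shaped trunk (bottleneck stages 3/4/6/3) with the
               final two stages dilated so the output stride is 8, widths
               scaled so the last stage emits ``agent_dim`` channels.
* ``deeplab``: the same trunk followed by an atrous spatial pyramid
               (rates 6/12/18) fused back to ``agent_dim`` channels.
* ``tiny``   : a 4-block strided conv net for CPU-scale experiments.

The decoder maps a (possibly fused) feature back to per-class probabilities:
two convolutions down to ``n_classes + 1`` channels, bilinear upsampling to
the input resolution, then a channel softmax.  Background occupies channel 0.

Normalisation is group-based throughout, so forward passes are independent
of batch composition and bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, GroupNorm2d, Module, ReLU, Sequential
from .profiles import ScaleProfile

__all__ = ["AgentEncoder", "AgentDecoder", "normalize_images"]

VARIANTS = ("fcn", "deeplab", "tiny")


def normalize_images(images: np.ndarray) -> Tensor:
    """Model-entry normalisation: integer 0..255 arrays to floats in [0,1].

    Accepts ``[3, S, S]`` or ``[N, 3, S, S]``; always returns a batched
    tensor."""
    a = np.asarray(images, dtype=np.float32)
    if a.ndim == 3:
        a = a[None]
    return Tensor(a / 255.0)


class _Bottleneck(Module):
    """ResNet bottleneck: 1x1 reduce, 3x3 (optionally dilated), 1x1 expand."""

    def __init__(self, cin: int, mid: int, cout: int,
                 rng: np.random.Generator, stride: int = 1,
                 dilation: int = 1):
        super().__init__()
        self.conv1 = Conv2d(cin, mid, 1, rng, bias=False)
        self.n1 = GroupNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, rng, stride=stride,
                            dilation=dilation, bias=False)
        self.n2 = GroupNorm2d(mid)
        self.conv3 = Conv2d(mid, cout, 1, rng, bias=False)
        self.n3 = GroupNorm2d(cout)
        self.proj = None
        if stride != 1 or cin != cout:
            self.proj = Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.nproj = GroupNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        out = self.n1(self.conv1(x)).relu()
        out = self.n2(self.conv2(out)).relu()
        out = self.n3(self.conv3(out))
        skip = x if self.proj is None else self.nproj(self.proj(x))
        return (out + skip).relu()


class _ResNetTrunk(Module):
    """ResNet-50-shaped trunk with output stride 8 (stages 3 and 4 dilated)."""

    def __init__(self, agent_dim: int, rng: np.random.Generator):
        super().__init__()
        if agent_dim % 8:
            raise ValueError("agent_dim must divide by 8 for the fcn trunk")
        stem = max(agent_dim // 32, 4)
        self.stem = Conv2d(3, stem, 7, rng, stride=2, bias=False)
        self.stem_n = GroupNorm2d(stem)
        blocks = (3, 4, 6, 3)
        couts = (agent_dim // 8, agent_dim // 4, agent_dim // 2, agent_dim)
        strides = (1, 2, 1, 1)
        dilations = (1, 1, 2, 4)
        self.stages = []
        cin = stem
        for si, (nb, cout, st, dil) in enumerate(
                zip(blocks, couts, strides, dilations)):
            mid = max(cout // 4, 4)
            layers = []
            for b in range(nb):
                layers.append(_Bottleneck(cin, mid, cout, rng,
                                          stride=st if b == 0 else 1,
                                          dilation=dil))
                cin = cout
            stage = Sequential(*layers)
            self._modules[f"stage{si}"] = stage
            self.stages.append(stage)

    def forward(self, x: Tensor) -> Tensor:
        x = self.stem_n(self.stem(x)).relu()
        x = x.max_pool2d(3, stride=2, padding=1)
        for stage in self.stages:
            x = stage(x)
        return x


class _ASPP(Module):
    """Atrous spatial pyramid pooling at the canonical rates 6/12/18."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        branch = max(dim // 8, 4)
        self.b0 = Conv2d(dim, branch, 1, rng, bias=False)
        self.b1 = Conv2d(dim, branch, 3, rng, dilation=6, bias=False)
        self.b2 = Conv2d(dim, branch, 3, rng, dilation=12, bias=False)
        self.b3 = Conv2d(dim, branch, 3, rng, dilation=18, bias=False)
        self.fuse = Conv2d(4 * branch, dim, 1, rng, bias=False)
        self.n = GroupNorm2d(dim)

    def forward(self, x: Tensor) -> Tensor:
        y = concat([self.b0(x), self.b1(x), self.b2(x), self.b3(x)], axis=1)
        return self.n(self.fuse(y.relu())).relu()


class _TinyTrunk(Module):
    """4-block strided conv net honouring the /8, agent_dim contract."""

    def __init__(self, agent_dim: int, rng: np.random.Generator):
        super().__init__()
        c1 = max(agent_dim // 2, 8)
        chans = [3, c1, c1, agent_dim, agent_dim]
        strides = [2, 2, 2, 1]
        layers = []
        for i, st in enumerate(strides):
            layers += [Conv2d(chans[i], chans[i + 1], 3, rng, stride=st,
                              bias=False),
                       GroupNorm2d(chans[i + 1]), ReLU()]
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class AgentEncoder(Module):
    """Maps ``[N, 3, S, S]`` images to agent features
    ``[N, agent_dim, S/8, S/8]``."""

    def __init__(self, profile: ScaleProfile, variant: str = "tiny",
                 seed: int = 0):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown agent variant {variant!r}")
        self.profile = profile
        self.variant = variant
        rng = np.random.default_rng([int(seed), 11])
        if variant == "tiny":
            self.trunk = _TinyTrunk(profile.agent_dim, rng)
            self.aspp = None
        else:
            self.trunk = _ResNetTrunk(profile.agent_dim, rng)
            self.aspp = _ASPP(profile.agent_dim, rng) \
                if variant == "deeplab" else None

    def forward(self, x: Tensor) -> Tensor:
        p = self.profile
        if x.shape[1:] != (3, p.input_side, p.input_side):
            raise ValueError(f"expected [N, 3, {p.input_side}, "
                             f"{p.input_side}], got {x.shape}")
        f = self.trunk(x)
        if self.aspp is not None:
            f = self.aspp(f)
        expected = (p.agent_dim, p.agent_grid, p.agent_grid)
        if f.shape[1:] != expected:
            raise RuntimeError(f"agent feature shape {f.shape[1:]} != "
                               f"{expected}")
        return f


class AgentDecoder(Module):
    """Two convolutions to class logits, bilinear upsampling, softmax."""

    def __init__(self, profile: ScaleProfile, seed: int = 0):
        super().__init__()
        self.profile = profile
        rng = np.random.default_rng([int(seed), 12])
        mid = max(profile.agent_dim // 4, 8)
        self.conv1 = Conv2d(profile.agent_dim, mid, 3, rng, bias=False)
        self.n1 = GroupNorm2d(mid)
        self.conv2 = Conv2d(mid, profile.n_classes + 1, 1, rng)

    def forward(self, fused: Tensor) -> Tensor:
        p = self.profile
        logits = self.conv2(self.n1(self.conv1(fused)).relu())
        logits = logits.resize_bilinear(p.input_side, p.input_side)
        return logits.softmax(axis=1)
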