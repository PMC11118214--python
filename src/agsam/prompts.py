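"""Feature fusion and automatic prompt generation.

This module houses the method's core machinery:

* ``ConfusionModule`` -- fuses the agent feature with the foundation image
  embedding: the embedding passes a 3x3 conv to the agent channel width, is
  bilinearly resized to the agent grid, concatenated channel-wise, and a
  1x1 conv halves the result back to ``agent_dim``.
* ``Facm`` -- the feature augmentation convolution module: a plain 3x3 conv
  whose output, during training with status ON, is randomly linearly
  suppressed: with probability ``p_zero`` it is zeroed; otherwise, with
  probability ``p_activate - p_zero``, it becomes ``alpha * c + beta`` with
  ``alpha ~ U(alpha_range)``, ``beta ~ U(beta_range)``.  OFF -- and any state
  at inference -- is exactly the bare convolution, so the module is
  parameter-free beyond its kernel.
* ``SparsePromptPath`` / ``DensePromptPath`` -- the two prompt-generation
  stacks: average pooling (factor 2), three stride-2 FACMs, four stride-1
  FACMs, and a final 1x1 conv, for a total spatial reduction of 1/16.  The
  sparse path consumes the agent's predicted mask and emits one token per
  class channel; the dense path consumes the fused feature and keeps the
  spatial layout of the foundation embedding grid.

The dense path compresses channels with a 1x1 conv *before* the bilinear
resize to full resolution.  A 1x1 convolution acts per-pixel on channels and
bilinear resampling mixes pixels linearly, so the two operations commute
exactly; compressing first avoids materialising an ``agent_dim`` x S x S
tensor at full scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concat
from .nn import Conv2d, Module
from .profiles import ScaleProfile

__all__ = ["FacmConfig", "PromptPathConfig", "Facm", "ConfusionModule",
           "SparsePromptPath", "DensePromptPath"]


@dataclass(frozen=True)
class FacmConfig:
    """Stochastic suppression parameters of a FACM layer.

    ``alpha`` draws are uniform on ``alpha_range`` (default [0.25, 1.0], so
    the mean suppression factor is 0.625); ``beta`` uniform on ``beta_range``
    (default [-10, 10], zero-mean).  ``status="OFF"`` behaves identically at
    train and inference time.
    """

    alpha_range: tuple[float, float] = (0.25, 1.0)
    beta_range: tuple[float, float] = (-10.0, 10.0)
    p_activate: float = 0.5
    p_zero: float = 0.05
    status: str = "ON"
    stride: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_zero <= self.p_activate <= 1.0):
            raise ValueError("need 0 <= p_zero <= p_activate <= 1")
        lo, hi = self.alpha_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("alpha_range must lie within (0, 1]")
        if self.status not in ("ON", "OFF"):
            raise ValueError("status must be 'ON' or 'OFF'")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")


@dataclass(frozen=True)
class PromptPathConfig:
    """Layer layout of the prompt-generation stacks.

    Seven FACMs; the first three have stride 2 and, together with the
    factor-2 average pooling, give the required total downsampling of 1/16.
    Only the layers listed in ``on_layers`` run with status ON (default: the
    first).  ``hidden`` is the internal channel width (unspecified by the
    architecture description; 16 suits the mini profile, 64 the full one).
    ``nonlinearity`` inserts a ReLU between FACMs; a fully linear path is
    available for algebraic tests.
    """

    n_facm: int = 7
    stride2_count: int = 3
    on_layers: frozenset = frozenset({0})
    pool_factor: int = 2
    hidden: int = 16
    nonlinearity: bool = True

    def __post_init__(self):
        if self.pool_factor * 2 ** self.stride2_count != 16:
            raise ValueError("pool_factor * 2^stride2_count must equal 16")
        if self.stride2_count > self.n_facm:
            raise ValueError("stride2_count cannot exceed n_facm")
        object.__setattr__(self, "on_layers", frozenset(self.on_layers))

    def all_off(self) -> "PromptPathConfig":
        return replace(self, on_layers=frozenset())


def draw_suppression(cfg: FacmConfig, rng_draw: int):
    """Sample the suppression decision for one forward pass.

    Returns ``(mode, alpha, beta)`` with mode in {"zero", "suppress",
    "identity"}; a pure function of ``(cfg.seed, rng_draw)``.
    """
    rng = np.random.default_rng([int(cfg.seed), int(rng_draw)])
    u = float(rng.uniform())
    if u < cfg.p_zero:
        return "zero", 0.0, 0.0
    if u < cfg.p_activate:
        alpha = float(rng.uniform(*cfg.alpha_range))
        beta = float(rng.uniform(*cfg.beta_range))
        return "suppress", alpha, beta
    return "identity", 1.0, 0.0


class Facm(Module):
    """One feature augmentation convolution module."""

    def __init__(self, cin: int, cout: int, cfg: FacmConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.conv = Conv2d(cin, cout, 3, rng, stride=cfg.stride)

    def forward(self, x: Tensor, rng_draw: int = 0,
                forced: tuple[float, float] | None = None) -> Tensor:
        c = self.conv(x)
        if self.cfg.status == "OFF" or not self.training:
            return c
        if forced is not None:
            alpha, beta = forced
            return c * alpha + beta
        mode, alpha, beta = draw_suppression(self.cfg, rng_draw)
        if mode == "zero":
            return c * 0.0
        if mode == "suppress":
            return c * alpha + beta
        return c


class ConfusionModule(Module):
    """Fuse agent feature and foundation embedding into one map of
    ``agent_dim`` channels on the agent grid."""

    def __init__(self, profile: ScaleProfile, seed: int = 0):
        super().__init__()
        self.profile = profile
        rng = np.random.default_rng([int(seed), 21])
        self.align = Conv2d(profile.sam_dim, profile.agent_dim, 3, rng)
        self.squeeze = Conv2d(2 * profile.agent_dim, profile.agent_dim,
                              1, rng)

    def forward(self, f_agent: Tensor, f_sam: Tensor) -> Tensor:
        p = self.profile
        if f_agent.shape[1:] != (p.agent_dim, p.agent_grid, p.agent_grid):
            raise ValueError(f"agent feature shape {f_agent.shape[1:]} does "
                             f"not match profile")
        if f_sam.shape[1:] != (p.sam_dim, p.sam_grid, p.sam_grid):
            raise ValueError(f"foundation embedding shape {f_sam.shape[1:]} "
                             f"does not match profile")
        aligned = self.align(f_sam).resize_bilinear(p.agent_grid,
                                                    p.agent_grid)
        return self.squeeze(concat([f_agent, aligned], axis=1))


class _PromptStack(Module):
    """Shared pool -> FACM x 7 -> 1x1 conv machinery of both paths."""

    def __init__(self, cin: int, cout_final: int, path_cfg: PromptPathConfig,
                 facm_cfg: FacmConfig, rng: np.random.Generator):
        super().__init__()
        self.path_cfg = path_cfg
        hid = path_cfg.hidden
        self.facms: list[Facm] = []
        c = cin
        for i in range(path_cfg.n_facm):
            stride = 2 if i < path_cfg.stride2_count else 1
            status = "ON" if i in path_cfg.on_layers else "OFF"
            layer = Facm(c, hid, replace(facm_cfg, stride=stride,
                                         status=status,
                                         seed=facm_cfg.seed + 101 * i), rng)
            self._modules[f"facm{i}"] = layer
            self.facms.append(layer)
            c = hid
        self.head = Conv2d(hid, cout_final, 1, rng)

    def forward(self, x: Tensor, rng_draw: int = 0) -> Tensor:
        x = x.avg_pool2d(self.path_cfg.pool_factor)
        for i, layer in enumerate(self.facms):
            x = layer(x, rng_draw=rng_draw)
            if self.path_cfg.nonlinearity and i < len(self.facms) - 1:
                x = x.relu()
        return self.head(x)


class SparsePromptPath(Module):
    """Agent mask -> per-class sparse prompt tokens
    ``[N, n_classes+1, prompt_dim]``."""

    def __init__(self, profile: ScaleProfile, path_cfg: PromptPathConfig,
                 facm_cfg: FacmConfig, seed: int = 0):
        super().__init__()
        if profile.input_side % 16:
            raise ValueError("input_side must divide by 16")
        self.profile = profile
        rng = np.random.default_rng([int(seed), 22])
        n_tok = profile.n_classes + 1
        self.stack = _PromptStack(n_tok, n_tok * profile.prompt_dim,
                                  path_cfg, facm_cfg, rng)

    def forward(self, mask_agent: Tensor, rng_draw: int = 0) -> Tensor:
        p = self.profile
        y = self.stack(mask_agent, rng_draw=rng_draw)   # [N, (n+1)*d, g, g]
        n = y.shape[0]
        # Arrange: spatial mean, then reshape to one token per class channel
        tokens = y.mean(axis=(2, 3)).reshape(n, p.n_classes + 1,
                                             p.prompt_dim)
        return tokens


class DensePromptPath(Module):
    """Fused feature -> dense prompt embedding
    ``[N, prompt_dim, sam_grid, sam_grid]``."""

    def __init__(self, profile: ScaleProfile, path_cfg: PromptPathConfig,
                 facm_cfg: FacmConfig, seed: int = 0):
        super().__init__()
        self.profile = profile
        rng = np.random.default_rng([int(seed), 23])
        self.compress = Conv2d(profile.agent_dim, path_cfg.hidden, 1, rng)
        self.stack = _PromptStack(path_cfg.hidden, profile.prompt_dim,
                                  path_cfg, facm_cfg, rng)

    def forward(self, f_fused: Tensor, rng_draw: int = 0) -> Tensor:
        p = self.profile
        x = self.compress(f_fused)                       # channels first;
        x = x.resize_bilinear(p.input_side, p.input_side)  # commutes exactly
        return self.stack(x, rng_draw=rng_draw + 7)      # decorrelated draws
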