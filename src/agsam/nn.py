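"""Neural-network layers, parameter management and AdamW on the autodiff core.

Layers mirror the conventional conv-net toolkit: ``Conv2d``, ``Linear``,
``GroupNorm2d``, ``LayerNorm``, multi-head attention, and a ``Sequential``
container.  Every layer draws its initial weights from an explicit
``numpy.random.Generator`` so that model construction is reproducible from a
single integer seed.  Normalisation is group/layer based (never batch based)
so that forward passes are independent of batch composition -- a requirement
for the bit-level determinism the test-suite asserts.
"""

from __future__ import annotations

import hashlib
import math
from typing import Iterable, Iterator

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Conv2d", "ConvTranspose2d", "Linear", "GroupNorm2d",
    "LayerNorm", "ReLU", "Sequential", "MultiHeadAttention", "AdamW",
    "checksum_state",
]


class Module:
    """Minimal parameter container with named sub-modules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, t: Tensor) -> Tensor:
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def freeze(self) -> "Module":
        """Stop all parameters from receiving updates (gradients still flow
        through frozen layers to their inputs)."""
        for p in self.parameters():
            p.requires_grad = False
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialisation ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            a = np.asarray(state[k], dtype=np.float32)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{a.shape} vs {p.data.shape}")
            p.data = a.copy()

    def save(self, path) -> None:
        np.savez(path, **{k.replace(".", "/"): v
                          for k, v in self.state_dict().items()})

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict({k.replace("/", "."): z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def checksum_state(module: Module) -> str:
    """SHA-256 over all parameter bytes, in name order."""
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


# -- layers --------------------------------------------------------------------


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 dilation: int = 1, bias: bool = True):
        super().__init__()
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = cin * k * k
        std = math.sqrt(2.0 / fan_in)
        self.register("weight", Tensor(
            rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True))
        self.bias = None
        if bias:
            self.register("bias_", Tensor(np.zeros(cout), requires_grad=True))
            self.bias = self.bias_

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 2, bias: bool = True):
        super().__init__()
        self.stride = stride
        std = math.sqrt(2.0 / (cin * k * k))
        self.register("weight", Tensor(
            rng.normal(0.0, std, (cin, cout, k, k)), requires_grad=True))
        self.bias = None
        if bias:
            self.register("bias_", Tensor(np.zeros(cout), requires_grad=True))
            self.bias = self.bias_

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        std = math.sqrt(2.0 / cin)
        self.register("weight", Tensor(
            rng.normal(0.0, std, (cin, cout)), requires_grad=True))
        self.bias = None
        if bias:
            self.register("bias_", Tensor(np.zeros(cout), requires_grad=True))
            self.bias = self.bias_

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm2d(Module):
    """Group normalisation over [N, C, H, W]; batch-composition independent."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        while channels % groups:
            groups //= 2
        self.groups, self.eps, self.channels = max(groups, 1), eps, channels
        self.register("gamma", Tensor(np.ones(channels), requires_grad=True))
        self.register("beta", Tensor(np.zeros(channels), requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        cent = xg - mu
        var = (cent * cent).mean(axis=2, keepdims=True)
        norm = cent * (var + self.eps).pow(-0.5)
        norm = norm.reshape(n, c, h, w)
        return norm * self.gamma.reshape(1, c, 1, 1) \
            + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.register("gamma", Tensor(np.ones(dim), requires_grad=True))
        self.register("beta", Tensor(np.zeros(dim), requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        cent = x - mu
        var = (cent * cent).mean(axis=-1, keepdims=True)
        return cent * (var + self.eps).pow(-0.5) * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MultiHeadAttention(Module):
    """Standard scaled dot-product attention, query/key/value projections."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must divide by heads")
        self.heads, self.dim = heads, dim
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        # inputs [T, dim] (single instance) or [N, T, dim]
        squeeze = q.ndim == 2
        if squeeze:
            q = q.reshape(1, *q.shape)
            k = k.reshape(1, *k.shape)
            v = v.reshape(1, *v.shape)
        n, tq, d = q.shape
        tk = k.shape[1]
        h = self.heads
        hd = d // h
        qp = self.q(q).reshape(n, tq, h, hd).transpose(0, 2, 1, 3)
        kp = self.k(k).reshape(n, tk, h, hd).transpose(0, 2, 1, 3)
        vp = self.v(v).reshape(n, tk, h, hd).transpose(0, 2, 1, 3)
        att = (qp @ kp.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        att = att.softmax(axis=-1)
        ctx = (att @ vp).transpose(0, 2, 1, 3).reshape(n, tq, d)
        out = self.out(ctx)
        return out.reshape(tq, d) if squeeze else out


# -- optimisation --------------------------------------------------------------


class AdamW:
    """AdamW with decoupled weight decay; operates on trainable params only."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
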