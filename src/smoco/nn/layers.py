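"""Neural-network layers built on the autodiff engine.

Modules mirror the conventional layer zoo at the scale this package
needs: 3D convolution, batch / group normalization, linear maps, ReLU
and 2x2x2 max pooling. Parameters are ``Tensor`` leaves with
``requires_grad=True``; buffers (running statistics) are plain arrays.
State dicts are flat ``name -> ndarray`` maps used by checkpoints and
by the momentum (EMA) parameter copy.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[name] = arr
        return arr

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for cn, child in self._children.items():
            yield from child.named_parameters(prefix + cn + ".")

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield prefix + n, b
        for cn, child in self._children.items():
            yield from child.named_buffers(prefix + cn + ".")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state dict -----------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.array(state[n], dtype=p.data.dtype)
        self._load_buffers(state, "")

    def _load_buffers(self, state, prefix):
        for n in list(self._buffers):
            self._buffers[n][...] = state["buf:" + prefix + n]
        for cn, child in self._children.items():
            child._load_buffers(state, prefix + cn + ".")

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = False, *, rng: np.random.Generator):
        super().__init__()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel ** 3
        self.weight = self.register_parameter(
            "weight", _he_normal(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = self.register_parameter("bias", np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.weight = self.register_parameter(
            "weight", _he_normal(rng, (in_dim, out_dim), in_dim))
        self.bias = self.register_parameter("bias", np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return ad.add(ad.matmul(x, self.weight), self.bias)


class BatchNorm3d(Module):
    """Per-channel normalization over (batch, depth, height, width).

    Batch statistics in training mode; exponential running statistics
    (momentum 0.1) in evaluation mode.
    """

    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = self.register_parameter("gamma", np.ones(n_ch))
        self.beta = self.register_parameter("beta", np.zeros(n_ch))
        self.register_buffer("running_mean", np.zeros(n_ch))
        self.register_buffer("running_var", np.ones(n_ch))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3, 4)
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm += self.momentum * (mu - rm)
            rv += self.momentum * (var - rv)
            return ad.norm_affine(x, self.gamma, self.beta, self.eps)
        return ad.norm_affine(x, self.gamma, self.beta, self.eps,
                              mu=self._buffers["running_mean"],
                              var=self._buffers["running_var"])


class GroupNorm3d(Module):
    """Per-sample group normalization; batch-size independent, hence
    stable for very small desk-scale batches."""

    def __init__(self, n_ch: int, n_groups: int = 4, eps: float = 1e-5):
        super().__init__()
        while n_ch % n_groups:
            n_groups -= 1
        self.n_groups, self.eps = n_groups, eps
        self.gamma = self.register_parameter("gamma", np.ones(n_ch))
        self.beta = self.register_parameter("beta", np.zeros(n_ch))

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        g = self.n_groups
        xg = ad.reshape(x, (B, g, C // g * D * H * W))
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc * ad.power(var + float(self.eps), -0.5)
        xn = ad.reshape(xn, (B, C, D, H, W))
        gamma = ad.reshape(self.gamma, (1, -1, 1, 1, 1))
        beta = ad.reshape(self.beta, (1, -1, 1, 1, 1))
        return xn * gamma + beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class MaxPool3d2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool3d_2(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._children[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


def make_norm(kind: str, n_ch: int) -> Module:
    if kind == "batch":
        return BatchNorm3d(n_ch)
    if kind == "group":
        return GroupNorm3d(n_ch)
    raise ValueError(f"unknown normalization kind: {kind!r}")
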