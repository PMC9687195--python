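"""Minimal neural-network layer library on top of :mod:`phf3.autograd`.

Mirrors the usual Module/parameter conventions: layers own named
:class:`~phf3.autograd.Tensor` parameters, compose hierarchically, expose
``state_dict``/``load_state_dict`` for checkpointing, and a ``train``/``eval``
mode flag that batch normalization respects.
"""

from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .autograd import (
    DEFAULT_DTYPE,
    Tensor,
    batch_norm2d,
    conv2d,
    layer_norm,
    max_pool2d,
)

__all__ = [
    "Module",
    "ModuleList",
    "Parameter",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "BatchNorm2d",
    "MaxPool2d",
    "Identity",
    "SGD",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=DEFAULT_DTYPE), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = np.asarray(array)
        object.__setattr__(self, name, self._buffers[name])

    # -- traversal ------------------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix=""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization --------------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = b.copy()
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, arr in state.items():
            if name in own:
                if own[name].data.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: "
                        f"{own[name].data.shape} vs {arr.shape}"
                    )
                own[name].data = np.asarray(arr, dtype=DEFAULT_DTYPE)
            elif name in bufs:
                bufs[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name}")
        missing = set(own) | set(bufs)
        missing -= set(state)
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True, *, rng, init="trunc_normal"):
        super().__init__()
        if init == "trunc_normal":
            w = _trunc_normal(rng, (out_features, in_features), std=0.02)
        else:  # kaiming fan-in for heads after ReLU-style features
            std = math.sqrt(2.0 / in_features)
            w = rng.normal(0.0, std, (out_features, in_features))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose()
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, groups=1,
                 bias=True, *, rng):
        super().__init__()
        fan_in = (in_ch // groups) * kernel * kernel
        std = math.sqrt(2.0 / fan_in)  # Kaiming normal, fan-in, ReLU gain
        self.weight = Parameter(
            rng.normal(0.0, std, (out_ch, in_ch // groups, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class BatchNorm2d(Module):
    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=DEFAULT_DTYPE))
        self.register_buffer("running_var", np.ones(num_features, dtype=DEFAULT_DTYPE))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.weight, self.bias,
                            self.running_mean, self.running_var,
                            self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, kernel=3, stride=2, padding=1):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Identity(Module):
    def forward(self, x):
        return x


def _trunc_normal(rng, shape, std=0.02, bound=2.0):
    """Normal(0, std) truncated to ±bound·std via resampling."""
    out = rng.normal(0.0, std, shape)
    bad = np.abs(out) > bound * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, int(bad.sum()))
        bad = np.abs(out) > bound * std
    return out


class SGD:
    """Stochastic gradient descent with classical momentum and decoupled-from-lr
    L2 weight decay (decay added to the gradient, as in the usual SGD form)."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"lr": self.lr, "momentum": self.momentum,
                "weight_decay": self.weight_decay,
                "velocity": [v.copy() for v in self._velocity]}

    def load_state_dict(self, state):
        self.lr = state["lr"]
        self.momentum = state["momentum"]
        self.weight_decay = state["weight_decay"]
        for v, sv in zip(self._velocity, state["velocity"]):
            v[...] = sv
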