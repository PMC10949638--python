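"""Parameterized layers on top of the autodiff tape.

Weight initialization draws from a process-local generator installed with
:func:`seed_init`; models built under the same seed get identical weights.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = [
    "seed_init",
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "SiLU",
    "Identity",
    "ConvBnAct",
    "SEBlock",
]

_INIT_RNG = np.random.default_rng(0)


@contextmanager
def seed_init(seed: int):
    """Install a fresh init generator for the duration of model construction."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = prev


class Module:
    """Minimal module: auto-registers Tensor parameters and sub-modules."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield f"{prefix}{name}", getattr(self, name)
        for name, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, b in self.named_buffers():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()) -> None:
        super().__init__()
        self._list: List[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def __len__(self):
        return len(self._list)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        padding: Optional[int] = None,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = True,
    ) -> None:
        super().__init__()
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.stride, self.padding, self.dilation, self.groups = (
            stride, padding, dilation, groups,
        )
        fan_in = (in_ch // groups) * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU-family activations
        self.weight = Tensor(
            _INIT_RNG.normal(0.0, std, size=(out_ch, in_ch // groups, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding,
            dilation=self.dilation, groups=self.groups,
        )


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(ch, dtype=np.float32))
        self.register_buffer("running_var", np.ones(ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm(
            x, self.gamma, self.beta,
            self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.silu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ConvBnAct(Module):
    """conv -> batch norm -> activation, the workhorse block."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        groups: int = 1,
        act: str = "relu",
    ) -> None:
        super().__init__()
        self.conv = Conv2d(
            in_ch, out_ch, kernel, stride=stride, dilation=dilation,
            groups=groups, bias=False,
        )
        self.bn = BatchNorm2d(out_ch)
        self.act = {"relu": ReLU, "silu": SiLU, "none": Identity}[act]()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class SEBlock(Module):
    """Squeeze-and-excitation: channel re-weighting from pooled descriptors."""

    def __init__(self, ch: int, reduction: int = 16) -> None:
        super().__init__()
        mid = max(ch // reduction, 4)
        self.fc1 = Conv2d(ch, mid, kernel=1, padding=0)
        self.fc2 = Conv2d(mid, ch, kernel=1, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        s = T.global_avg_pool(x)
        s = T.relu(self.fc1(s))
        s = T.sigmoid(self.fc2(s))
        return T.mul(x, s)
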