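"""Neural-network building blocks on top of the autograd tensor.

Follows the familiar Module/parameter idiom: assigning a :class:`Parameter`
or a :class:`Module` to an attribute registers it, ``parameters()`` walks the
tree, and ``state_dict``/``load_state_dict`` round-trip flat name->array
mappings (saved with ``numpy.savez``).
"""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Sequential",
    "Conv2d", "Linear", "InstanceNorm2d",
    "ReLU", "LeakyReLU", "Tanh",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def freeze(self) -> None:
        """Stop gradient accumulation on all parameters (they still pass
        gradients through to their inputs); stale gradients are dropped."""
        for p in self.parameters():
            p.requires_grad = False
            p.grad = None

    @property
    def frozen(self) -> bool:
        params = self.parameters()
        return bool(params) and all(not p.requires_grad for p in params)

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def checksum(self) -> str:
        """SHA-256 over all parameter bytes, in name order."""
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        setattr(self, str(len(self._items)), module)
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self._items:
            x = m(x)
        return x


def _init_weight(shape, fan_in: int, scheme: str, rng: np.random.Generator):
    if scheme == "he":
        std = np.sqrt(2.0 / fan_in)
    elif scheme == "gan":   # DCGAN/CycleGAN convention
        std = 0.02
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, bias: bool = True, init: str = "he",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            _init_weight((out_ch, in_ch, kernel, kernel), fan_in, init, rng))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, init: str = "he",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_init_weight((in_f, out_f), in_f, init, rng))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    No affine parameters (the CycleGAN reference convention); implemented
    compositionally so its gradient comes from the primitive ops.
    """

    def __init__(self, eps: float = 1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xm = x - mu
        var = (xm * xm).mean(axis=(2, 3), keepdims=True)
        return xm * ((var + self.eps) ** -0.5)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.tanh()
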