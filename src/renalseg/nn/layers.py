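"""Layer/module abstractions over the functional primitives."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "Dropout",
    "MaxPool3d",
    "ReLU",
    "Sequential",
]


class Module:
    """Minimal module: parameter discovery via attributes, train/eval mode,
    and a shared RNG for stochastic layers (dropout)."""

    def __init__(self) -> None:
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        seen: set[int] = set()

        def visit(prefix: str, m: "Module"):
            for name, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad and id(v) not in seen:
                    seen.add(id(v))
                    out.append((f"{prefix}{name}", v))
                elif isinstance(v, Module):
                    visit(f"{prefix}{name}.", v)
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(f"{prefix}{name}.{i}.", item)

        visit("", self)
        return out

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, m in enumerate(self.modules()):
            for name, v in m.__dict__.items():
                if isinstance(v, np.ndarray):
                    out.append((f"{i}.{name}", v))
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def set_rng(self, rng: np.random.Generator) -> "Module":
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.buffers():
            state[f"buf:{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], np.float32).copy()
        for name, buf in self.buffers():
            key = f"buf:{name}"
            if key in state:
                buf[...] = state[key]

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 3, pad: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.pad = kernel // 2 if pad is None else pad
        fan_in = cin * kernel**3
        self.weight = Tensor(_he_init(rng, (cout, cin, kernel, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, pad=self.pad)


class ConvTranspose3d(Module):
    def __init__(self, cin: int, cout: int, kernel: int = 2, stride: int = 2,
                 pad: int = 0, output_padding: int = 0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.pad, self.output_padding = stride, pad, output_padding
        fan_in = cin * kernel**3
        self.weight = Tensor(_he_init(rng, (cin, cout, kernel, kernel, kernel), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, stride=self.stride,
                                  pad=self.pad, output_padding=self.output_padding)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class Dropout(Module):
    def __init__(self, p: float = 0.2, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class MaxPool3d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool3d(x, self.size)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
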