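"""Layer/module abstractions over the autodiff core.

Mirrors the familiar torch.nn surface at a miniature scale: ``Module`` with
``parameters()`` / ``train()`` / ``eval()`` / ``state_dict()``, plus the
concrete layers the keypoint networks use.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import DTYPE, Tensor


class Module:
    """Base class; submodules and parameters are discovered by attribute scan."""

    def __init__(self) -> None:
        self.training = True

    # -- traversal ---------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
        for name, child in self.children():
            yield from child.buffers(f"{prefix}{name}.")

    # -- mode --------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self.children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer::{name}": b.copy() for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                bufs[key[len("buffer::"):]][...] = value
            else:
                params[key].data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def count_parameters(module: Module) -> int:
    """Exact count of parameter scalars (trainability does not affect the count)."""
    return int(sum(p.data.size for p in module.parameters()))


class Conv2d(Module):
    """2-D convolution with 'same'-style explicit padding and optional bias.

    He-normal weight initialization, zero bias.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int] | int,
                 stride: int | tuple[int, int] = 1,
                 padding: tuple[int, int] | None = None,
                 bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        if isinstance(stride, int):
            stride = (stride, stride)
        if padding is None:  # preserve spatial size at stride 1
            padding = (kernel_size[0] // 2, kernel_size[1] // 2)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size[0] * kernel_size[1]
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, *kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for step in self.steps:
            x = step(x)
        return x


class ConvBNReLU(Sequential):
    """The stock conv -> batch-norm -> ReLU unit used throughout the backbone."""

    def __init__(self, cin: int, cout: int, kernel: int | tuple[int, int],
                 stride: int = 1, rng=None, relu: bool = True):
        steps = [Conv2d(cin, cout, kernel, stride, bias=False, rng=rng),
                 BatchNorm2d(cout)]
        if relu:
            steps.append(ReLU())
        super().__init__(*steps)
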