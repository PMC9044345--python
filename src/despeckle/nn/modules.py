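"""Layer abstractions over the autograd engine: Conv2d, BatchNorm2d, Module."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "BatchNorm2d", "ConvBNReLU"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with parameter/buffer traversal and train/eval switching."""

    def __init__(self) -> None:
        self.training = True

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                out.extend(value.named_buffers(f"{full}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(f"{full}.{i}."))
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                out.append((full, value))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- modes -------------------------------------------------------------
    def train(self) -> "Module":
        return self._apply_mode(True)

    def eval(self) -> "Module":
        return self._apply_mode(False)

    def _apply_mode(self, training: bool) -> "Module":
        self.training = training
        for value in vars(self).values():
            if isinstance(value, Module):
                value._apply_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._apply_mode(training)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data for k, v in self.named_parameters()}
        state.update({f"buffer.{k}": v for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r} in checkpoint")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(params[name].data.dtype)
            elif kind == "buffer":
                if name not in buffers:
                    raise KeyError(f"unknown buffer {name!r} in checkpoint")
                buffers[name][...] = value
            else:  # pragma: no cover
                raise KeyError(f"malformed state key {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Conv2d(Module):
    """2-D convolution with He-normal initialization.

    ``bias`` should be False whenever a BatchNorm follows: the BN
    mean-subtraction makes such a bias unidentifiable (its gradient is
    identically zero).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        *,
        stride: int = 1,
        padding=0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        # NHWC engine layout: weights are (kh, kw, in_ch, out_ch)
        w = rng.standard_normal((kernel_size, kernel_size, in_channels, out_channels), dtype=np.float32)
        w *= np.float32(std)  # in place: the full-width plan has ~5e8 weights
        self.weight = Parameter(w if np.dtype(dtype) == np.float32 else w.astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ConvBNReLU(Module):
    """The conv -> batch norm -> ReLU unit used throughout both networks."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *, stride: int = 1, padding=0, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(
            in_channels, out_channels, kernel_size, stride=stride, padding=padding, bias=False, rng=rng, dtype=dtype
        )
        self.bn = BatchNorm2d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))
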