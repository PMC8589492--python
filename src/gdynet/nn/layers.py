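"""Neural-network modules over the autodiff engine.

Initialization follows He/Kaiming fan-in scaling; every builder takes a
``numpy.random.Generator`` so construction is deterministic under a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "Linear", "Sequential", "ReLU",
           "Sigmoid"]


class Parameter(Tensor):
    """A tensor registered as trainable."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter/buffer discovery, state dicts,
    and a train/eval mode flag (used by normalization running stats)."""

    _buffer_names: tuple[str, ...] = ()

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
        for name, child in self._children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffer_names:
            yield f"{prefix}{name}", getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def set_training(self, flag: bool) -> None:
        if hasattr(self, "training"):
            self.training = bool(flag)
        for _, child in self._children():
            child.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer/{k}": v.copy()
                      for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        from .autograd import get_default_dtype
        own = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = set(own) | {f"buffer/{k}" for k in buffers}
        missing = expected ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=get_default_dtype()).copy()
        for k in buffers:
            arr = np.asarray(state[f"buffer/{k}"], dtype=np.float64)
            parts = k.split(".")
            target: Module = self
            for part in parts[:-1]:
                if part.isdigit():
                    target = target[int(part)]  # type: ignore[index]
                else:
                    target = getattr(target, part)
            setattr(target, parts[-1], arr.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...],
             fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, *,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator):
        if c_in % groups or c_out % groups:
            raise ValueError(
                f"groups={groups} must divide c_in={c_in} and c_out={c_out}")
        fan_in = (c_in // groups) * kernel * kernel
        self.weight = Parameter(
            _he_init(rng, (c_out, c_in // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        self.weight = Parameter(_he_init(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization with affine parameters.

    Per-sample statistics (no batch coupling), so inference is
    deterministic and independent of batch composition.  Built from
    primitive autograd ops; its gradients are covered by the same
    finite-difference oracle as everything else.
    """

    def __init__(self, channels: int, groups: int | None = None):
        if groups is None:
            groups = next(g for g in (8, 4, 2, 1) if channels % g == 0)
        if channels % groups:
            raise ValueError(f"groups={groups} must divide {channels}")
        self.groups = groups
        self.channels = channels
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, (c // g) * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        y = xc * ((var + 1e-5) ** -0.5)
        return y.reshape(n, c, h, w) * self.gamma + self.beta


class BatchNorm1d(Module):
    """Batch normalization over feature vectors (N, F).

    In training mode, batch statistics normalize the features and update
    exponential running statistics; in eval mode the running statistics
    are used, so inference is deterministic and batch-independent.  The
    running statistics can also be set exactly from a reference feature
    matrix via :meth:`calibrate` (done once after training, which removes
    the small-batch train/eval statistics gap).
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n))
        self.beta = Parameter(np.zeros(n))
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.training = False   # eval by default; train() flips it
        self.last_input: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        self.last_input = x.data.copy()
        if self.training and x.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (mu.data[0]
                                                  - self.running_mean)
            self.running_var += self.momentum * (var.data[0]
                                                 - self.running_var)
            y = xc * ((var + self.eps) ** -0.5)
        else:
            y = (x - Tensor(self.running_mean[None])) \
                * Tensor(1.0 / np.sqrt(self.running_var[None] + self.eps))
        return y * self.gamma + self.beta

    def calibrate(self, features: np.ndarray) -> None:
        """Set running statistics exactly from a feature matrix (N, F)."""
        self.running_mean = features.mean(axis=0).astype(np.float64)
        self.running_var = features.var(axis=0).astype(np.float64)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
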