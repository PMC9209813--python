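"""Minimal layer/module system with explicit backward passes.

Modules cache what their backward pass needs during forward; calling
``backward(dy)`` returns the input gradient and accumulates parameter
gradients in-place.  Everything is float32 NCHW.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

DTYPE = np.float32


class Parameter:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: parameter collection, train/eval mode, grad reset."""

    def __init__(self) -> None:
        self.training = True

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def parameters(self) -> list[Parameter]:
        out = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self._children():
            out.extend(child.parameters())
        return out

    def train(self, flag: bool = True):
        self.training = flag
        for child in self._children():
            child.train(flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, v in mod.__dict__.items():
                if isinstance(v, Parameter):
                    out[prefix + name] = v.data
                elif isinstance(v, np.ndarray):  # running stats
                    out[prefix + name] = v
                elif isinstance(v, Module):
                    walk(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, u in enumerate(v):
                        if isinstance(u, Module):
                            walk(u, f"{prefix}{name}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]} ...")
        for key, arr in state.items():
            own[key][...] = arr

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """Variance-preserving fan-in (He) normal initialization."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, dilation: int = 1):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride, self.dilation = stride, dilation
        self.pad = dilation * (k - 1) // 2  # 'same' for stride 1
        self.w = Parameter(he_init(rng, (cout, cin, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cols = F.conv2d(x, self.w.data, self.b.data, self.stride,
                           self.dilation, self.pad, return_cols=True)
        self._cache = (cols, x.shape) if self.training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        self.w.grad += F.conv2d_dw(cols, dy, self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return F.conv2d_dx(dy, self.w.data, self.stride, self.dilation,
                           self.pad, x_shape[2], x_shape[3])


class ConvTranspose2d(Module):
    """3x3 stride-2 transposed convolution doubling the spatial size."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 2, pad: int = 1, out_pad: int = 1):
        super().__init__()
        self.k, self.stride, self.pad, self.out_pad = k, stride, pad, out_pad
        self.w = Parameter(he_init(rng, (cin, cout, k, k), cin * k * k))
        self.b = Parameter(np.zeros(cout))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cols = F.conv_transpose2d(x, self.w.data, self.b.data, self.stride,
                                     self.pad, self.out_pad, return_cols=True)
        self._cache = cols if self.training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += F.conv_transpose2d_dw(self._cache, dy, self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return F.conv_transpose2d_dx(dy, self.w.data, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cache = F.batchnorm_forward(
            x, self.gamma.data, self.beta.data, self.running_mean,
            self.running_var, self.training, self.momentum, self.eps,
        )
        self._cache = cache if self.training else None
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dgamma, dbeta = F.batchnorm_backward(dy, self.gamma.data, self._cache)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        return dx.astype(DTYPE, copy=False)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mask = x > 0
        self._mask = mask if self.training else None
        return np.where(mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.mods:
            x = m(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.mods):
            dy = m.backward(dy)
        return dy


def conv_block(cin: int, cout: int, k: int, rng: np.random.Generator,
               stride: int = 1, dilation: int = 1, bn: bool = True,
               relu: bool = True) -> Sequential:
    """Convolution -> batch normalization -> ReLU."""
    mods: list[Module] = [Conv2d(cin, cout, k, rng, stride, dilation)]
    if bn:
        mods.append(BatchNorm2d(cout))
    if relu:
        mods.append(ReLU())
    return Sequential(*mods)


def transposed_conv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    """Transposed convolution -> batch normalization -> ReLU (upsampling)."""
    return Sequential(ConvTranspose2d(cin, cout, rng), BatchNorm2d(cout), ReLU())
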