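"""Minimal NumPy neural-network engine for 1-D convolutional models.

Implements exactly the layer set the seizure-classification architecture
needs — strided/dilated 1-D convolutions, batch normalization, ReLU,
dropout, global max pooling, a differential-entropy pooling layer, and a
linear head — each with a hand-derived backward pass, plus an Adam
optimizer with L2 weight decay and global gradient-norm clipping.

All tensors are float32.  Convolutions are evaluated as ``k`` BLAS matrix
products over dilated strided slices rather than via an im2col buffer,
which keeps memory flat and throughput high on a single CPU.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: tracks sub-modules and parameters, toggles train/eval."""

    def __init__(self) -> None:
        self.training = True

    def children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def parameters(self) -> list[Parameter]:
        out = [v for v in self.__dict__.values() if isinstance(v, Parameter)]
        for child in self.children():
            out.extend(child.parameters())
        return out

    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name->array mapping of parameters and buffers."""
        out: dict[str, np.ndarray] = {}
        self._collect_state("", out)
        return out

    def _collect_state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                out[prefix + k] = v.data
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                out[prefix + k] = v
            elif isinstance(v, Module):
                v._collect_state(prefix + k + ".", out)
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        m._collect_state(f"{prefix}{k}.{i}.", out)

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)[:5]}")
        self._assign_state("", state)

    def _assign_state(self, prefix: str, state: dict[str, np.ndarray]) -> None:
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                v.data[...] = state[prefix + k]
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                v[...] = state[prefix + k]
            elif isinstance(v, Module):
                v._assign_state(prefix + k + ".", state)
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        m._assign_state(f"{prefix}{k}.{i}.", state)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv1d(Module):
    """1-D convolution (cross-correlation) with stride and dilation.

    Bias-free: every convolution in the architecture is followed by batch
    normalization, whose shift absorbs any bias.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, dilation: int = 1, padding: int = 0,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            he_init(rng, (out_channels, in_channels, kernel_size),
                    in_channels * kernel_size))
        self._cache: tuple | None = None

    def out_length(self, T: int) -> int:
        eff = (self.kernel_size - 1) * self.dilation + 1
        return (T + 2 * self.padding - eff) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, T = x.shape
        if C != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {C}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        T_out = self.out_length(T)
        if T_out < 1:
            raise ValueError(f"input length {T} too short for kernel span")
        W = self.weight.data
        y = np.zeros((N, self.out_channels, T_out), dtype=DTYPE)
        span = (T_out - 1) * self.stride + 1
        for i in range(self.kernel_size):
            off = i * self.dilation
            xi = xp[:, :, off:off + span:self.stride]
            # (out,in) @ (in, N*T_out)
            y += np.matmul(W[:, :, i], xi.transpose(1, 0, 2).reshape(C, -1)) \
                .reshape(self.out_channels, N, T_out).transpose(1, 0, 2)
        self._cache = (xp, T, T_out)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, T, T_out = self._cache
        N, C = xp.shape[0], self.in_channels
        W = self.weight.data
        dyt = dy.transpose(1, 0, 2).reshape(self.out_channels, -1)
        dxp = np.zeros_like(xp)
        span = (T_out - 1) * self.stride + 1
        for i in range(self.kernel_size):
            off = i * self.dilation
            xi = xp[:, :, off:off + span:self.stride]
            self.weight.grad[:, :, i] += np.matmul(
                dyt, xi.transpose(1, 0, 2).reshape(C, -1).T)
            dxi = np.matmul(W[:, :, i].T, dyt) \
                .reshape(C, N, T_out).transpose(1, 0, 2)
            dxp[:, :, off:off + span:self.stride] += dxi
        p = self.padding
        return dxp[:, :, p:p + T] if p else dxp


class BatchNorm(Module):
    """Batch normalization over (N, C, T) or (N, C) inputs.

    Channel statistics are taken over all non-channel axes; population
    (biased) variance is used both for normalization and for the running
    buffers, which serve at evaluation time.
    """

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, dtype=DTYPE))
        self.beta = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        is3d = x.ndim == 3
        axes = (0, 2) if is3d else (0,)
        shape = (1, -1, 1) if is3d else (1, -1)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mean
            self.running_var[...] = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        y = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)
        if self.training:
            self._cache = (xhat, inv_std, axes, shape)
        return y.astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        M = dy.size // self.num_features
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self.gamma.data.reshape(shape)
        s1 = dxhat.sum(axis=axes).reshape(shape)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(shape)
        dx = (dxhat - s1 / M - xhat * s2 / M) * inv_std.reshape(shape)
        return dx.astype(DTYPE, copy=False)


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE, copy=False)


class Dropout(Module):
    """Inverted dropout; identity at evaluation time.

    Randomness comes from a generator injected by the owning network so a
    single training seed drives every stochastic layer.
    """

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator = np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return (x * self._mask).astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE, copy=False)


class GlobalMaxPool(Module):
    """Per-channel maximum over the temporal axis: (N, C, T) -> (N, C)."""

    def __init__(self) -> None:
        super().__init__()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        idx = x.argmax(axis=2)
        self._cache = (idx, x.shape)
        return np.take_along_axis(x, idx[:, :, None], axis=2)[:, :, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        dx = np.zeros(shape, dtype=DTYPE)
        np.put_along_axis(dx, idx[:, :, None], dy[:, :, None], axis=2)
        return dx


class MaxPool1d(Module):
    """Non-overlapping temporal max pooling with window = stride."""

    def __init__(self, window: int) -> None:
        super().__init__()
        self.window = window
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, T = x.shape
        T_out = T // self.window
        xr = x[:, :, :T_out * self.window].reshape(N, C, T_out, self.window)
        idx = xr.argmax(axis=3)
        self._cache = (idx, x.shape, T_out)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, shape, T_out = self._cache
        N, C, T = shape
        dxr = np.zeros((N, C, T_out, self.window), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=3)
        dx = np.zeros(shape, dtype=DTYPE)
        dx[:, :, :T_out * self.window] = dxr.reshape(N, C, -1)
        return dx


class DifferentialEntropyPool(Module):
    """Per-channel differential entropy over time: (N, C, T) -> (N, C).

    Computes H = 0.5 * ln(2*pi*e*(s2 + eps)) with s2 the unbiased (N-1
    denominator) temporal variance.  Fully differentiable, so gradients
    reach the convolutional trunk through the statistical pathway.
    """

    def __init__(self, eps: float = 1e-6) -> None:
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[2]
        if T < 2:
            raise ValueError("differential entropy needs at least 2 samples")
        centered = x - x.mean(axis=2, keepdims=True)
        var = (centered ** 2).sum(axis=2) / (T - 1)
        self._cache = (centered, var, T)
        return (0.5 * np.log(2.0 * np.pi * np.e * (var + self.eps))) \
            .astype(DTYPE, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        centered, var, T = self._cache
        coef = dy * 0.5 / (var + self.eps)            # dH/d(var)
        dx = coef[:, :, None] * (2.0 / (T - 1)) * centered
        return dx.astype(DTYPE, copy=False)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            he_init(rng, (out_features, in_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.data).astype(DTYPE, copy=False)


# ---------------------------------------------------------------------------
# optimization


def global_grad_norm(params: list[Parameter]) -> float:
    total = 0.0
    for p in params:
        total += float(np.sum(p.grad.astype(np.float64) ** 2))
    return float(np.sqrt(total))


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    norm = global_grad_norm(params)
    if norm > max_norm and norm > 0.0:
        scale = DTYPE(max_norm / norm)
        for p in params:
            p.grad *= scale
    return norm


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + DTYPE(self.weight_decay) * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.data -= DTYPE(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
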