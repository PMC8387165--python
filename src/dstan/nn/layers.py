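"""Feed-forward layers with explicit forward/backward passes."""

from __future__ import annotations

import numpy as np

from dstan.nn import _kernels

_WARMED = False


def _use_numba() -> bool:
    global _WARMED
    if _kernels.HAVE_NUMBA and not _WARMED:
        _kernels.warmup()
        _WARMED = True
    return _kernels.HAVE_NUMBA


class Parameter:
    """A learnable tensor and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class; collects Parameters recursively from attributes."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def astype(self, dtype) -> "Module":
        """Convert all parameters (and BN running stats) in place."""
        for value in vars(self).values():
            if isinstance(value, Parameter):
                value.data = value.data.astype(dtype)
                value.grad = value.grad.astype(dtype)
            elif isinstance(value, Module):
                value.astype(dtype)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.astype(dtype)
        if isinstance(self, BatchNorm2d):
            self.running_mean = self.running_mean.astype(dtype)
            self.running_var = self.running_var.astype(dtype)
        return self

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value.data
            elif isinstance(value, Module):
                out.update(value.state_arrays(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        if isinstance(self, BatchNorm2d):
            out[f"{prefix}running_mean"] = self.running_mean
            out[f"{prefix}running_var"] = self.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                value.data = np.asarray(arrays[key], dtype=value.data.dtype)
                value.grad = np.zeros_like(value.data)
            elif isinstance(value, Module):
                value.load_state_arrays(arrays, f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, f"{key}.{i}.")
        if isinstance(self, BatchNorm2d):
            self.running_mean = np.asarray(
                arrays[f"{prefix}running_mean"], dtype=self.running_mean.dtype
            )
            self.running_var = np.asarray(
                arrays[f"{prefix}running_var"], dtype=self.running_var.dtype
            )


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix for stride-1 same convolution.

    Patch-major layout so the convolution is a single large GEMM.
    """
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    if _use_numba():
        cols = np.empty((n * h * w, c * k * k), dtype=x.dtype)
        _kernels.im2col_kernel(np.ascontiguousarray(xp), k, h, w, cols)
        return cols
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, h, w, k, k) -> (n, h, w, c, k, k) -> (n*h*w, c*k*k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    if _use_numba():
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
        _kernels.col2im_kernel(np.ascontiguousarray(dcols), k, h, w, dxp)
        return np.ascontiguousarray(dxp[:, :, pad : pad + h, pad : pad + w]) if pad else dxp
    dc = dcols.reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dc[:, :, :, :, i, j]
    dxp = dxp[:, pad : pad + h, pad : pad + w, :] if pad else dxp
    return np.ascontiguousarray(dxp.transpose(0, 3, 1, 2))


class Conv2d(Module):
    """Stride-1 convolution with zero padding preserving H and W (odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError("only odd kernel sizes are supported")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            (rng.standard_normal((out_channels, in_channels, kernel_size, kernel_size)) * scale
             ).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"channel mismatch: kernel expects {self.in_channels}, got {x.shape[1]}"
            )
        n, _, h, w = x.shape
        cols = _im2col(x, self.kernel_size, self.pad)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ w2.T
        out += self.bias.data
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            out.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.out_channels
        )
        self.bias.grad += dmat.sum(axis=0)
        self.weight.grad += (dmat.T @ cols).reshape(self.weight.data.shape)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        dcols = dmat @ w2
        return _col2im(dcols, x_shape, self.kernel_size, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        n_elem = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv_std[None, :, None, None]
        # batch statistics participate in the forward pass during training
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_elem
        )
        return term * inv_std[None, :, None, None]


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2x2(Module):
    """2x2 max pooling with stride 2; input H, W must be even."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size must be even for 2x2 pooling, got {h}x{w}")
        if _use_numba():
            x = np.ascontiguousarray(x)
            out = np.empty((n, c, h // 2, w // 2), dtype=x.dtype)
            idx = np.empty((n, c, h // 2, w // 2), dtype=np.uint8)
            _kernels.maxpool_forward_kernel(x, out, idx)
            self._x, self._out, self._idx = x, out, idx
            return out
        self._idx = None
        self._x = x
        s = (x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2],
             x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2])
        out = np.maximum(np.maximum(s[0], s[1]), np.maximum(s[2], s[3]))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, out = self._x, self._out
        dx = np.zeros_like(x)
        if self._idx is not None:
            _kernels.maxpool_backward_kernel(np.ascontiguousarray(dout), self._idx, dx)
            return dx
        remaining = dout  # route each output's gradient to the first matching max
        taken = np.zeros(dout.shape, dtype=bool)
        for di in (0, 1):
            for dj in (0, 1):
                sl = x[:, :, di::2, dj::2]
                hit = (sl == out) & ~taken
                view = dx[:, :, di::2, dj::2]
                view[hit] = dout[hit]
                taken |= hit
        del remaining
        return dx


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C) channel-wise spatial mean."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape).astype(dout.dtype) / (h * w)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter((rng.standard_normal((out_features, in_features)) * scale
                                 ).astype(dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data
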