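"""Optional numba-compiled kernels for the memory-bound inner loops.

The pure-NumPy implementations in `layers.py` are the reference; these fused
single-pass loops compute exactly the same values (same order of scalar
operations per output element, no fastmath reassociation), just without the
intermediate arrays. If numba is unavailable the module exposes HAVE_NUMBA =
False and the layers fall back to NumPy.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def im2col_kernel(xp, k, h, w, cols):  # pragma: no cover - compiled
    """Gather patches from the already zero-padded (n, c, h+2p, w+2p) input."""
    n, c = xp.shape[0], xp.shape[1]
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                row = (ni * h + i) * w + j
                col = 0
                for ci in range(c):
                    for ki in range(k):
                        for kj in range(k):
                            cols[row, col] = xp[ni, ci, i + ki, j + kj]
                            col += 1


@njit(cache=False)
def col2im_kernel(dcols, k, h, w, dxp):  # pragma: no cover - compiled
    """Scatter-add patch gradients into a zero-padded (n, c, h+2p, w+2p) buffer."""
    n, c = dxp.shape[0], dxp.shape[1]
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                row = (ni * h + i) * w + j
                col = 0
                for ci in range(c):
                    for ki in range(k):
                        for kj in range(k):
                            dxp[ni, ci, i + ki, j + kj] += dcols[row, col]
                            col += 1


@njit(cache=False)
def maxpool_forward_kernel(x, out, idx):  # pragma: no cover - compiled
    n, c, ho, wo = out.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    best = x[ni, ci, 2 * i, 2 * j]
                    arg = 0
                    v = x[ni, ci, 2 * i, 2 * j + 1]
                    if v > best:
                        best = v
                        arg = 1
                    v = x[ni, ci, 2 * i + 1, 2 * j]
                    if v > best:
                        best = v
                        arg = 2
                    v = x[ni, ci, 2 * i + 1, 2 * j + 1]
                    if v > best:
                        best = v
                        arg = 3
                    out[ni, ci, i, j] = best
                    idx[ni, ci, i, j] = arg


@njit(cache=False)
def maxpool_backward_kernel(dout, idx, dx):  # pragma: no cover - compiled
    n, c, ho, wo = dout.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(ho):
                for j in range(wo):
                    a = idx[ni, ci, i, j]
                    di = a // 2
                    dj = a % 2
                    dx[ni, ci, 2 * i + di, 2 * j + dj] = dout[ni, ci, i, j]


def warmup() -> None:
    """Trigger JIT compilation on tiny inputs (called lazily by the layers)."""
    if not HAVE_NUMBA:
        return
    x = np.zeros((1, 1, 4, 4), dtype=np.float32)
    xp = np.zeros((1, 1, 6, 6), dtype=np.float32)
    cols = np.zeros((16, 9), dtype=np.float32)
    im2col_kernel(xp, 3, 4, 4, cols)
    col2im_kernel(cols, 3, 4, 4, xp)
    out = np.zeros((1, 1, 2, 2), dtype=np.float32)
    idx = np.zeros((1, 1, 2, 2), dtype=np.uint8)
    dx = np.zeros_like(x)
    maxpool_forward_kernel(x, out, idx)
    maxpool_backward_kernel(out, idx, dx)
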