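"""The three attention mechanisms of the dual-stream network.

* Multiscale-kernel spatial attention: a per-pixel sigmoid weight map built
  from parallel 1x1, 3x3 and 5x5 convolutions of a low-level feature map,
  fused by a 1x1 convolution — S_m = Conv_m(F^l), SA = sigma(Conv4([S1,S2,S3])),
  F_S = SA (*) F^l with SA broadcast across channels.
* Global dual-pool channel attention: per-channel sigmoid weights from a
  shared two-layer bottleneck (compression ratio r) applied to the GAP and
  GMP descriptors and summed — C_b = w2 relu(w1 pool + b1) + b2,
  CA = sigma(C1 + C2), F_C = CA (*) F^h with CA broadcast across pixels.
* Temporal attention: one sigmoid scalar per frame, r_i = sigma(u . S_i + b),
  rescaling each frame's spatial feature vector before the recurrent model.
  Weights are per-frame sigmoids, not softmax — there is no cross-frame
  normalisation.

Each block is a trainable `Module` (forward/backward) used inside the streams,
plus a functional wrapper operating on a single (batch-free) feature map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dstan.nn.layers import Conv2d, Module, Parameter


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class FeatureMap:
    """A (C, H, W) feature map tagged with its network level."""

    values: np.ndarray
    level: str = "low"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be (C, H, W), got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("feature map contains non-finite values")


class SpatialAttention(Module):
    """Multiscale-kernel spatial attention over a low-level feature map."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        self.channels = channels
        self.conv1 = Conv2d(channels, 1, 1, rng, dtype)
        self.conv2 = Conv2d(channels, 1, 3, rng, dtype)
        self.conv3 = Conv2d(channels, 1, 5, rng, dtype)
        self.conv4 = Conv2d(3, 1, 1, rng, dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        s1 = self.conv1.forward(x, train)
        s2 = self.conv2.forward(x, train)
        s3 = self.conv3.forward(x, train)
        cat = np.concatenate([s1, s2, s3], axis=1)
        sa = _sigmoid(self.conv4.forward(cat, train))
        self._cache = (x, sa)
        self.weight_map = sa
        return sa * x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, sa = self._cache
        dsa = (dout * x).sum(axis=1, keepdims=True)
        dz = dsa * sa * (1.0 - sa)
        dcat = self.conv4.backward(dz)
        dx = self.conv1.backward(dcat[:, 0:1])
        dx += self.conv2.backward(dcat[:, 1:2])
        dx += self.conv3.backward(dcat[:, 2:3])
        dx += sa * dout
        return dx


class ChannelAttention(Module):
    """Global dual-pool channel attention with a shared bottleneck MLP."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator,
                 dtype=np.float32):
        if channels % ratio != 0:
            raise ValueError(f"channels ({channels}) must be divisible by ratio ({ratio})")
        self.channels = channels
        self.ratio = ratio
        hidden = channels // ratio
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        self.w1 = Parameter((rng.standard_normal((hidden, channels)) * s1).astype(dtype))
        self.b1 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = Parameter((rng.standard_normal((channels, hidden)) * s2).astype(dtype))
        self.b2 = Parameter(np.zeros(channels, dtype=dtype))
        self._cache = None

    def _mlp(self, v: np.ndarray):
        h = v @ self.w1.data.T + self.b1.data
        a = np.maximum(h, 0.0)
        return a @ self.w2.data.T + self.b2.data, (v, h, a)

    def _mlp_backward(self, dout: np.ndarray, cache) -> np.ndarray:
        v, h, a = cache
        self.w2.grad += dout.T @ a
        self.b2.grad += dout.sum(axis=0)
        da = dout @ self.w2.data
        dh = da * (h > 0)
        self.w1.grad += dh.T @ v
        self.b1.grad += dh.sum(axis=0)
        return dh @ self.w1.data

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        gap = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, h * w)
        argmax = flat.argmax(axis=2)
        gmp = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        c1, cache1 = self._mlp(gap)
        c2, cache2 = self._mlp(gmp)
        ca = _sigmoid(c1 + c2)
        self._cache = (x, ca, argmax, cache1, cache2)
        self.gap_vector, self.gmp_vector = gap, gmp
        self.weight_vector = ca
        return ca[:, :, None, None] * x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, ca, argmax, cache1, cache2 = self._cache
        n, c, h, w = x.shape
        dca = (dout * x).sum(axis=(2, 3))
        dz = dca * ca * (1.0 - ca)
        dgap = self._mlp_backward(dz, cache1)
        dgmp = self._mlp_backward(dz, cache2)
        dx = ca[:, :, None, None] * dout
        dx += dgap[:, :, None, None] / (h * w)
        dflat = dx.reshape(n, c, h * w)
        idx_n = np.arange(n)[:, None]
        idx_c = np.arange(c)[None, :]
        dflat[idx_n, idx_c, argmax] += dgmp
        return dflat.reshape(n, c, h, w)


class TemporalAttention(Module):
    """Per-frame sigmoid gate r_i = sigma(u . S_i + b) applied to (N, t, d)."""

    def __init__(self, feature_dim: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(1.0 / feature_dim)
        self.u = Parameter((rng.standard_normal(feature_dim) * scale).astype(dtype))
        self.b = Parameter(np.zeros(1, dtype=dtype))
        self._cache = None

    def forward(self, s: np.ndarray, train: bool = False) -> np.ndarray:
        r = _sigmoid(s @ self.u.data + self.b.data[0])
        self._cache = (s, r)
        self.frame_weights = r
        return r[..., None] * s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        s, r = self._cache
        dr = (dout * s).sum(axis=-1)
        dz = dr * r * (1.0 - r)
        ds = r[..., None] * dout + dz[..., None] * self.u.data
        self.u.grad += np.tensordot(dz, s, axes=(range(dz.ndim), range(dz.ndim)))
        self.b.grad += dz.sum()
        return ds


# ---------------------------------------------------------------------------
# Functional wrappers on single feature maps / sequences
# ---------------------------------------------------------------------------

def multiscale_spatial_attention(fmap: FeatureMap, state: SpatialAttention
                                 ) -> tuple[FeatureMap, SpatialAttention]:
    """Refine a (C, H, W) low-level map; returns (refined map, state).

    After the call, `state.weight_map` holds the (1, H, W) sigmoid map SA.
    """
    refined = state.forward(fmap.values[None], train=False)[0]
    state.weight_map = state.weight_map[0]
    return FeatureMap(refined, level=fmap.level), state


def dual_pool_channel_attention(fmap: FeatureMap, state: ChannelAttention
                                ) -> tuple[FeatureMap, ChannelAttention]:
    """Refine a (C, H, W) high-level map; returns (refined map, state)."""
    refined = state.forward(fmap.values[None], train=False)[0]
    state.gap_vector = state.gap_vector[0]
    state.gmp_vector = state.gmp_vector[0]
    state.weight_vector = state.weight_vector[0]
    return FeatureMap(refined, level=fmap.level), state


def temporal_attention(frame_features: np.ndarray, state: TemporalAttention
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Weight a (t, d) stack of frame features; returns (weighted, weights)."""
    frame_features = np.asarray(frame_features)
    if frame_features.ndim != 2:
        raise ValueError(f"frame features must be (t, d), got {frame_features.shape}")
    weighted = state.forward(frame_features[None], train=False)[0]
    weights = state.frame_weights[0]
    state.frame_weights = weights
    return weighted, weights
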