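"""Independent brute-force oracles used to validate the network layers.

Everything here is written against the defining formulas directly — explicit
loops and scipy.signal.correlate2d — and never calls into the dstan.nn
forward paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import correlate2d


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def conv2d_oracle(x: np.ndarray, weight: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Stride-1 zero-padded convolution of one (C, H, W) map: loops + correlate2d."""
    f, c, _, _ = weight.shape
    out = np.zeros((f, x.shape[1], x.shape[2]))
    for fi in range(f):
        acc = np.zeros(x.shape[1:], dtype=np.float64)
        for ci in range(c):
            acc += correlate2d(x[ci].astype(np.float64),
                               weight[fi, ci].astype(np.float64), mode="same")
        out[fi] = acc + float(bias[fi])
    return out


def spatial_attention_oracle(x: np.ndarray, state) -> tuple[np.ndarray, np.ndarray]:
    """Direct evaluation of the multiscale spatial attention on one (C, H, W) map."""
    s1 = conv2d_oracle(x, state.conv1.weight.data, state.conv1.bias.data)
    s2 = conv2d_oracle(x, state.conv2.weight.data, state.conv2.bias.data)
    s3 = conv2d_oracle(x, state.conv3.weight.data, state.conv3.bias.data)
    cat = np.concatenate([s1, s2, s3], axis=0)
    sa = sigmoid(conv2d_oracle(cat, state.conv4.weight.data, state.conv4.bias.data))
    return sa * x, sa


def channel_attention_oracle(x: np.ndarray, state) -> tuple[np.ndarray, np.ndarray]:
    """Direct evaluation of the dual-pool channel attention on one (C, H, W) map."""
    c = x.shape[0]
    gap = np.array([x[ci].mean() for ci in range(c)])
    gmp = np.array([x[ci].max() for ci in range(c)])

    def mlp(v):
        h = state.w1.data.astype(np.float64) @ v + state.b1.data
        h = np.maximum(h, 0.0)
        return state.w2.data.astype(np.float64) @ h + state.b2.data

    ca = sigmoid(mlp(gap) + mlp(gmp))
    return ca[:, None, None] * x, ca


def temporal_attention_oracle(s: np.ndarray, u: np.ndarray, b: float
                              ) -> tuple[np.ndarray, np.ndarray]:
    """r_i = sigmoid(u . S_i + b); weighted S_i' = r_i S_i, per frame."""
    t = s.shape[0]
    weights = np.array([sigmoid(float(np.dot(u, s[i]) + b)) for i in range(t)])
    return weights[:, None] * s, weights


def maxpool_oracle(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    out = np.zeros((c, h // 2, w // 2))
    for ci in range(c):
        for i in range(h // 2):
            for j in range(w // 2):
                out[ci, i, j] = x[ci, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max()
    return out


def batchnorm_eval_oracle(x: np.ndarray, bn) -> np.ndarray:
    g = bn.gamma.data[:, None, None].astype(np.float64)
    b = bn.beta.data[:, None, None].astype(np.float64)
    m = bn.running_mean[:, None, None].astype(np.float64)
    v = bn.running_var[:, None, None].astype(np.float64)
    return g * (x - m) / np.sqrt(v + bn.eps) + b


def _block_oracle(net, i, x):
    h = conv2d_oracle(x, net.convs[i].weight.data, net.convs[i].bias.data)
    h = batchnorm_eval_oracle(h, net.bns[i])
    h = np.maximum(h, 0.0)
    return maxpool_oracle(h)


def stream_frame_forward_oracle(net, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode per-frame spatial feature recomputed layer by layer."""
    h = x.astype(np.float64)
    for i in range(3):
        h = _block_oracle(net, i, h)
    low_map = h
    if net.kind == "motion":
        if net.spatial_attn is not None:
            h, _ = spatial_attention_oracle(low_map, net.spatial_attn)
        for i in (3, 4):
            h = _block_oracle(net, i, h)
        if net.channel_attn is not None:
            h, _ = channel_attention_oracle(h, net.channel_attn)
        return np.array([h[ci].mean() for ci in range(h.shape[0])])
    h = low_map
    for i in (3, 4):
        h = _block_oracle(net, i, h)
    high_map = h
    if net.low_conv is not None:
        low = low_map
        if net.spatial_attn is not None:
            low, _ = spatial_attention_oracle(low, net.spatial_attn)
        low = conv2d_oracle(low, net.low_conv.weight.data, net.low_conv.bias.data)
        low_vec = np.array([low[ci].mean() for ci in range(low.shape[0])])
        high = high_map
        if net.channel_attn is not None:
            high, _ = channel_attention_oracle(high, net.channel_attn)
        high = conv2d_oracle(high, net.high_conv.weight.data, net.high_conv.bias.data)
        high_vec = np.array([high[ci].mean() for ci in range(high.shape[0])])
        return np.concatenate([low_vec, high_vec])
    high = high_map
    if net.channel_attn is not None:
        high, _ = channel_attention_oracle(high, net.channel_attn)
    return np.array([high[ci].mean() for ci in range(high.shape[0])])


def lstm_oracle(lstm, s: np.ndarray) -> np.ndarray:
    """Hidden-state sequence of the single-layer LSTM for one (t, d) input."""
    hs_dim = lstm.hidden_size
    wx = lstm.w_x.data.astype(np.float64)
    wh = lstm.w_h.data.astype(np.float64)
    bias = lstm.bias.data.astype(np.float64)
    h = np.zeros(hs_dim)
    c = np.zeros(hs_dim)
    out = []
    for k in range(s.shape[0]):
        z = wx @ s[k] + wh @ h + bias
        i = sigmoid(z[:hs_dim])
        f = sigmoid(z[hs_dim : 2 * hs_dim])
        g = np.tanh(z[2 * hs_dim : 3 * hs_dim])
        o = sigmoid(z[3 * hs_dim :])
        c = f * c + i * g
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.stack(out)


def sequence_forward_oracle(model, frames: np.ndarray) -> dict:
    """Full evaluation-mode forward for one (t, C, H, W) sample."""
    net = model.net
    feats = np.stack([stream_frame_forward_oracle(net, f) for f in frames])
    if net.temporal_attn is not None:
        feats, weights = temporal_attention_oracle(
            feats, net.temporal_attn.u.data.astype(np.float64),
            float(net.temporal_attn.b.data[0]),
        )
    else:
        weights = np.ones(len(frames))
    hs = lstm_oracle(net.lstm, feats)
    f = hs.mean(axis=0)
    logits = net.classifier.weight.data.astype(np.float64) @ f + net.classifier.bias.data
    e = np.exp(logits - logits.max())
    return {"f": f, "step_outputs": hs, "logits": logits, "proba": e / e.sum(),
            "weights": weights}


def sequence_forward_oracle_from_features(model, feats: np.ndarray) -> dict:
    """Temporal model only: attention + LSTM + mean pooling + classifier."""
    net = model.net
    s = feats.astype(np.float64)
    if net.temporal_attn is not None:
        s, _ = temporal_attention_oracle(
            s, net.temporal_attn.u.data.astype(np.float64),
            float(net.temporal_attn.b.data[0]))
    hs = lstm_oracle(net.lstm, s)
    f = hs.mean(axis=0)
    logits = net.classifier.weight.data.astype(np.float64) @ f + net.classifier.bias.data
    e = np.exp(logits - logits.max())
    return {"f": f, "step_outputs": hs, "logits": logits, "proba": e / e.sum()}


def metrics_tally_oracle(y_true, y_pred, classes) -> dict:
    """Accuracy and macro precision/recall/F1 from explicit per-class counting."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    precs, recs, f1s = [], [], []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        precs.append(prec)
        recs.append(rec)
    k = len(classes)
    return {"accuracy": acc, "precision": sum(precs) / k, "recall": sum(recs) / k,
            "f1": sum(f1s) / k}
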