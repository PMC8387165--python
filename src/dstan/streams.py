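"""The two spatiotemporal streams.

STAN-A (appearance) and STMN-A (motion) share a lightweight backbone: five
blocks of [zero-pad 3x3 conv -> batch norm -> ReLU -> 2x2 max-pool stride 2].
The motion stream refines the block-3 map with multiscale spatial attention
and the block-5 map with dual-pool channel attention in place, then global
average pooling gives the per-frame spatial feature. The appearance stream
adds the low/high feature-fusion path (LHFN): the block-3 map, refined by
spatial attention, goes through a 1x1 convolution and GAP to a low-level
texture vector; the block-5 map, refined by channel attention, through a 1x1
convolution and GAP to a high-level semantic vector; the frame feature is
their concatenation. The backbone itself continues from the unrefined block-3
map, so attention shapes only the fused descriptor.

Temporally, per-frame features are gated by temporal attention, consumed by a
single-layer LSTM, and averaged over steps (temporal average pooling)
f = (1/t) sum_i v_i; an affine classifier plus softmax yields class
probabilities. Training is minibatch Adam on cross-entropy, fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from dstan.attention import ChannelAttention, SpatialAttention, TemporalAttention
from dstan.data import DegenerateInputError
from dstan.nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    LSTM,
    MaxPool2x2,
    Module,
    ReLU,
    softmax,
    softmax_cross_entropy,
)

CHECKPOINT_VERSION = 1


@dataclass
class StreamConfig:
    """Architecture and training settings for one stream."""

    input_channels: int = 1
    conv_widths: tuple[int, ...] = (32, 64, 128, 256, 512)
    lstm_hidden: int = 256
    num_classes: int = 3
    ratio: int = 16
    t: int = 9
    frame_size: tuple[int, int] = (224, 224)
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    use_spatial_attention: bool = True
    use_channel_attention: bool = True
    use_temporal_attention: bool = True
    use_lhfn: bool = True
    feature_kind: str = "feature"  # which output feeds fusion: feature|logits|proba

    def __post_init__(self) -> None:
        self.conv_widths = tuple(self.conv_widths)
        self.frame_size = tuple(self.frame_size)
        if len(self.conv_widths) != 5:
            raise ValueError("conv_widths must have exactly 5 entries")
        for dim in self.frame_size:
            if dim % 32 != 0:
                raise ValueError(f"frame size {self.frame_size} must be divisible by 32")
        if self.conv_widths[4] % self.ratio != 0:
            raise ValueError(
                f"conv_widths[4]={self.conv_widths[4]} must be divisible by ratio={self.ratio}"
            )
        if self.feature_kind not in ("feature", "logits", "proba"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")


@dataclass
class SequenceFeature:
    """Outputs of the temporal model for one sample."""

    vector: np.ndarray            # f = mean of step outputs
    step_outputs: np.ndarray      # (t, hidden) LSTM hidden states v_i
    logits: np.ndarray            # (num_classes,)
    probabilities: np.ndarray     # softmax(logits)


@dataclass
class StreamFeatures:
    """Per-sample sequence features for a whole dataset, in dataset order."""

    sample_ids: list[str]
    subject_ids: list[str]
    labels: np.ndarray
    features: np.ndarray       # (n, d) fusion features (per config.feature_kind)
    probabilities: np.ndarray  # (n, num_classes)
    logits: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "subject_id": self.subject_ids,
             "label": self.labels}
        )
        for j in range(self.features.shape[1]):
            df[f"f{j}"] = self.features[:, j]
        return df

    def predictions(self) -> np.ndarray:
        """Per-stream softmax predictions (argmax, lowest index on ties)."""
        return self.probabilities.argmax(axis=1)


class _StreamNet(Module):
    """The trainable network behind one stream."""

    def __init__(self, config: StreamConfig, kind: str, rng: np.random.Generator):
        if kind not in ("appearance", "motion"):
            raise ValueError(f"unknown stream kind {kind!r}")
        self.kind = kind
        widths = config.conv_widths
        in_ch = [config.input_channels, *widths[:-1]]
        self.convs = [Conv2d(in_ch[i], widths[i], 3, rng) for i in range(5)]
        self.bns = [BatchNorm2d(widths[i]) for i in range(5)]
        self.relus = [ReLU() for _ in range(5)]
        self.pools = [MaxPool2x2() for _ in range(5)]
        self.spatial_attn = SpatialAttention(widths[2], rng) if config.use_spatial_attention else None
        self.channel_attn = (
            ChannelAttention(widths[4], config.ratio, rng)
            if config.use_channel_attention else None
        )
        self.gap = GlobalAvgPool()
        if kind == "appearance" and config.use_lhfn:
            self.low_conv = Conv2d(widths[2], widths[2], 1, rng)
            self.high_conv = Conv2d(widths[4], widths[4], 1, rng)
            self.low_gap = GlobalAvgPool()
            self.feature_dim = widths[2] + widths[4]
        else:
            self.low_conv = None
            self.high_conv = None
            self.low_gap = None
            self.feature_dim = widths[4]
        self.temporal_attn = (
            TemporalAttention(self.feature_dim, rng)
            if config.use_temporal_attention else None
        )
        self.lstm = LSTM(self.feature_dim, config.lstm_hidden, rng)
        self.classifier = Linear(config.lstm_hidden, config.num_classes, rng)

    # ---- per-frame spatial model -------------------------------------

    def _block(self, i: int, h: np.ndarray, train: bool) -> np.ndarray:
        h = self.convs[i].forward(h, train)
        h = self.bns[i].forward(h, train)
        h = self.relus[i].forward(h, train)
        return self.pools[i].forward(h, train)

    def forward_frames(self, x: np.ndarray, train: bool) -> np.ndarray:
        """(N, C, H, W) -> (N, feature_dim); caches for backward_frames."""
        h = x
        for i in range(3):
            h = self._block(i, h, train)
        low_map = h
        if self.kind == "motion":
            # attention refines the main path in place
            if self.spatial_attn is not None:
                h = self.spatial_attn.forward(low_map, train)
            for i in (3, 4):
                h = self._block(i, h, train)
            if self.channel_attn is not None:
                h = self.channel_attn.forward(h, train)
            return self.gap.forward(h, train)
        # appearance stream: backbone continues from the unrefined block-3 map
        h = low_map
        for i in (3, 4):
            h = self._block(i, h, train)
        high_map = h
        if self.low_conv is not None:
            low = low_map
            if self.spatial_attn is not None:
                low = self.spatial_attn.forward(low, train)
            low = self.low_conv.forward(low, train)
            low_vec = self.low_gap.forward(low, train)
            high = high_map
            if self.channel_attn is not None:
                high = self.channel_attn.forward(high, train)
            high = self.high_conv.forward(high, train)
            high_vec = self.gap.forward(high, train)
            return np.concatenate([low_vec, high_vec], axis=1)
        high = high_map
        if self.channel_attn is not None:
            high = self.channel_attn.forward(high, train)
        return self.gap.forward(high, train)

    def backward_frames(self, dfeat: np.ndarray) -> None:
        if self.kind == "motion":
            dmap = self.gap.backward(dfeat)
            if self.channel_attn is not None:
                dmap = self.channel_attn.backward(dmap)
            for i in (4, 3):
                dmap = self.pools[i].backward(dmap)
                dmap = self.relus[i].backward(dmap)
                dmap = self.bns[i].backward(dmap)
                dmap = self.convs[i].backward(dmap)
            if self.spatial_attn is not None:
                dmap = self.spatial_attn.backward(dmap)
            for i in (2, 1, 0):
                dmap = self.pools[i].backward(dmap)
                dmap = self.relus[i].backward(dmap)
                dmap = self.bns[i].backward(dmap)
                dmap = self.convs[i].backward(dmap)
            return
        # appearance stream
        if self.low_conv is not None:
            dlow_vec = dfeat[:, : self.low_conv.out_channels]
            dhigh_vec = dfeat[:, self.low_conv.out_channels :]
            dhigh = self.gap.backward(dhigh_vec)
            dhigh = self.high_conv.backward(dhigh)
            if self.channel_attn is not None:
                dhigh = self.channel_attn.backward(dhigh)
            dlow = self.low_gap.backward(dlow_vec)
            dlow = self.low_conv.backward(dlow)
            if self.spatial_attn is not None:
                dlow = self.spatial_attn.backward(dlow)
        else:
            dhigh = self.gap.backward(dfeat)
            if self.channel_attn is not None:
                dhigh = self.channel_attn.backward(dhigh)
            dlow = None
        dmap = dhigh
        for i in (4, 3):
            dmap = self.pools[i].backward(dmap)
            dmap = self.relus[i].backward(dmap)
            dmap = self.bns[i].backward(dmap)
            dmap = self.convs[i].backward(dmap)
        if dlow is not None:
            dmap = dmap + dlow  # block-3 output feeds both block 4 and the low branch
        for i in (2, 1, 0):
            dmap = self.pools[i].backward(dmap)
            dmap = self.relus[i].backward(dmap)
            dmap = self.bns[i].backward(dmap)
            dmap = self.convs[i].backward(dmap)

    # ---- temporal model ----------------------------------------------

    def forward_sequences(self, x: np.ndarray, train: bool
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(B, t, C, H, W) -> (logits, f, step_outputs (t, B, hidden))."""
        b, t = x.shape[:2]
        feats = self.forward_frames(x.reshape(b * t, *x.shape[2:]), train)
        s = feats.reshape(b, t, -1)
        if self.temporal_attn is not None:
            s = self.temporal_attn.forward(s, train)
        hs = self.lstm.forward(np.ascontiguousarray(s.transpose(1, 0, 2)), train)
        f = hs.mean(axis=0)
        logits = self.classifier.forward(f, train)
        return logits, f, hs

    def backward_sequences(self, dlogits: np.ndarray, shape: tuple) -> None:
        b, t = shape[:2]
        df = self.classifier.backward(dlogits)
        dhs = np.broadcast_to(df[None], (t, *df.shape)).astype(df.dtype) / t
        ds = self.lstm.backward(np.ascontiguousarray(dhs))
        ds = np.ascontiguousarray(ds.transpose(1, 0, 2))
        if self.temporal_attn is not None:
            ds = self.temporal_attn.backward(ds)
        self.backward_frames(ds.reshape(b * t, -1))


@dataclass
class TrainedStream:
    """A stream network plus its configuration and training log."""

    net: _StreamNet
    config: StreamConfig
    kind: str
    training_log: list[float] = field(default_factory=list)

    @property
    def feature_dim(self) -> int:
        return self.net.feature_dim


def build_stream(config: StreamConfig, stream_kind: str) -> TrainedStream:
    rng = np.random.default_rng(config.seed)
    return TrainedStream(net=_StreamNet(config, stream_kind, rng),
                         config=config, kind=stream_kind)


# ---------------------------------------------------------------------------
# Spec-level operations
# ---------------------------------------------------------------------------

def stmn_spatial_forward(flow_frame: np.ndarray, model: TrainedStream) -> np.ndarray:
    """Per-frame spatial feature of the motion stream for one (2, H, W) input."""
    if model.kind != "motion":
        raise ValueError("stmn_spatial_forward requires a motion stream")
    _check_frame(flow_frame, model)
    return np.asarray(model.net.forward_frames(flow_frame[None].astype(np.float32),
                                               train=False)[0])


def stan_spatial_forward(frame: np.ndarray, model: TrainedStream) -> np.ndarray:
    """Per-frame spatial feature of the appearance stream for one (C, H, W) input."""
    if model.kind != "appearance":
        raise ValueError("stan_spatial_forward requires an appearance stream")
    _check_frame(frame, model)
    return np.asarray(model.net.forward_frames(frame[None].astype(np.float32),
                                               train=False)[0])


def _check_frame(frame: np.ndarray, model: TrainedStream) -> None:
    if frame.ndim != 3:
        raise ValueError(f"frame must be (C, H, W), got {frame.shape}")
    _, h, w = frame.shape
    if h % 32 or w % 32:
        raise ValueError(f"spatial size {h}x{w} must be divisible by 32 (five 2x poolings)")


def temporal_forward(frame_features: np.ndarray, model: TrainedStream) -> SequenceFeature:
    """Temporal model on a (t, d) stack of per-frame spatial features."""
    frame_features = np.asarray(frame_features, dtype=np.float32)
    if frame_features.size == 0 or frame_features.ndim != 2:
        raise DegenerateInputError("need a non-empty (t, d) feature stack")
    net = model.net
    s = frame_features[None]
    if net.temporal_attn is not None:
        s = net.temporal_attn.forward(s, train=False)
    hs = net.lstm.forward(np.ascontiguousarray(s.transpose(1, 0, 2)), train=False)
    f = hs.mean(axis=0)[0]
    logits = net.classifier.forward(f[None], train=False)[0]
    return SequenceFeature(vector=f, step_outputs=hs[:, 0, :], logits=logits,
                           probabilities=softmax(logits))


class StreamDataset:
    """Tensorised sequences ready for a stream: x (N, t, C, H, W), y (N,)."""

    def __init__(self, x: np.ndarray, y: np.ndarray, sample_ids: list[str],
                 subject_ids: list[str]):
        self.x = np.asarray(x, dtype=np.float32)
        self.y = np.asarray(y, dtype=np.int64)
        self.sample_ids = list(sample_ids)
        self.subject_ids = list(subject_ids)
        if self.x.ndim != 5:
            raise ValueError(f"x must be (N, t, C, H, W), got {self.x.shape}")
        if len(self.x) != len(self.y):
            raise ValueError("x and y length mismatch")

    def __len__(self) -> int:
        return len(self.y)


def train_stream(dataset: StreamDataset, config: StreamConfig,
                 stream_kind: str) -> TrainedStream:
    """Train one stream with Adam on cross-entropy; reproducible under config.seed."""
    classes = np.unique(dataset.y)
    if classes.size < 2:
        raise ValueError(f"training needs >=2 classes, got {classes.size}")
    if dataset.x.shape[3] % 32 or dataset.x.shape[4] % 32:
        raise ValueError("frame size must be divisible by 32")
    model = build_stream(config, stream_kind)
    if config.epochs == 0:
        return model
    params = model.net.parameters()
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(dataset)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = dataset.x[idx]
            yb = dataset.y[idx]
            opt.zero_grad()
            logits, _, _ = model.net.forward_sequences(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            model.net.backward_sequences(dlogits.astype(np.float32), xb.shape)
            opt.step()
            losses.append(loss)
        model.training_log.append(float(np.mean(losses)))
    return model


def extract_stream_features(model: TrainedStream, dataset: StreamDataset,
                            batch_size: int = 32) -> StreamFeatures:
    """Evaluation-mode sequence features for every sample, in dataset order."""
    if dataset.x.shape[3:] != tuple(model.config.frame_size):
        raise ValueError(
            f"frame size {dataset.x.shape[3:]} does not match config "
            f"{model.config.frame_size}"
        )
    feats, probs, logits_all = [], [], []
    for start in range(0, len(dataset), batch_size):
        xb = dataset.x[start : start + batch_size]
        logits, f, _ = model.net.forward_sequences(xb, train=False)
        feats.append(f)
        logits_all.append(logits)
        probs.append(softmax(logits))
    f = np.concatenate(feats)
    logits = np.concatenate(logits_all)
    p = np.concatenate(probs)
    fusion_feat = {"feature": f, "logits": logits, "proba": p}[model.config.feature_kind]
    return StreamFeatures(
        sample_ids=dataset.sample_ids,
        subject_ids=dataset.subject_ids,
        labels=dataset.y.copy(),
        features=np.asarray(fusion_feat, dtype=np.float64),
        probabilities=np.asarray(p, dtype=np.float64),
        logits=np.asarray(logits, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_stream(model: TrainedStream, path) -> None:
    """Single-file checkpoint: npz archive with a JSON config header."""
    header = json.dumps(
        {
            "version": CHECKPOINT_VERSION,
            "kind": model.kind,
            "config": asdict(model.config),
            "training_log": model.training_log,
        }
    )
    arrays = model.net.state_arrays()
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_stream(path) -> TrainedStream:
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__header__"}
    if header["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {header['version']}")
    cfg_dict = header["config"]
    config = StreamConfig(**cfg_dict)
    model = build_stream(config, header["kind"])
    model.net.load_state_arrays(arrays)
    model.training_log = list(header["training_log"])
    return model
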