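"""Loading, spatial/temporal normalisation and dense optical flow.

Micro-expression clips arrive with varying lengths and frame sizes; the
streams need fixed-shape tensors. Temporal normalisation resamples each pixel
trajectory piecewise-linearly at uniform fractional positions (an
endpoint-preserving temporal interpolation model), spatial normalisation is
bilinear resampling, and the motion stream consumes dense optical flow
between adjacent frames of the normalised sequence, so both streams share
geometry. Face detection/alignment is deliberately a pass-through hook: the
package expects pre-cropped, pre-aligned faces and lets callers plug their
own aligner.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Callable, Mapping

import imageio.v3 as iio
import numpy as np
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk, optical_flow_tvl1
from skimage.transform import resize

from dstan.data import DegenerateInputError, FlowSequence, FrameSequence

#: clip bound (pixels) used when encoding flow for the motion stream
FLOW_CLIP = 8.0

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    try:
        img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise IOError(f"could not read frame {path}: {exc}") from exc
    img = np.asarray(img)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    elif img.dtype == np.uint16:
        img = img.astype(np.float64) / 65535.0
    else:
        img = img.astype(np.float64)
    return np.clip(img, 0.0, 1.0)


def load_sequence(path: str | os.PathLike, label_row: Mapping,
                  align_hook: Callable[[np.ndarray], np.ndarray] | None = None
                  ) -> FrameSequence:
    """Load one sample from a frame directory (lexicographic order) or video file.

    `label_row` must provide sample_id, subject_id and label. `align_hook`,
    if given, is applied per frame (H, W, C); the default is a no-op — frames
    are expected pre-cropped and aligned.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in _IMAGE_EXTENSIONS and not p.name.startswith(".")
        )
        if len(files) < 2:
            raise DegenerateInputError(
                f"{path} holds {len(files)} readable frames; need at least 2"
            )
        frames = [_read_image(p) for p in files]
    elif path.exists():
        try:
            video = iio.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"could not decode video {path}: {exc}") from exc
        frames = [np.asarray(f, dtype=np.float64) for f in video]
        if frames and frames[0].max() > 1.0:
            frames = [f / 255.0 for f in frames]
        if len(frames) < 2:
            raise DegenerateInputError(f"video {path} has {len(frames)} frames; need >= 2")
    else:
        raise IOError(f"no such file or directory: {path}")
    stacked = []
    for f in frames:
        if align_hook is not None:
            f = np.asarray(align_hook(f))
        if f.ndim == 2:
            f = f[:, :, None]
        stacked.append(f)
    return FrameSequence(
        frames=np.clip(np.stack(stacked), 0.0, 1.0),
        subject_id=str(label_row["subject_id"]),
        sample_id=str(label_row["sample_id"]),
        label=int(label_row["label"]),
        source_fps=float(label_row["fps"]) if "fps" in label_row else None,
    )


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def spatial_normalize(seq: FrameSequence, size: tuple[int, int]) -> FrameSequence:
    """Bilinear resampling of every frame to (height, width)."""
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"target size must be positive, got {size}")
    if seq.frames.shape[1:3] == (h, w):
        frames = seq.frames.copy()
    else:
        frames = np.stack(
            [
                resize(frame, (h, w), order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True)
                for frame in seq.frames
            ]
        )
    return FrameSequence(
        frames=np.clip(frames, 0.0, 1.0),
        subject_id=seq.subject_id, sample_id=seq.sample_id, label=seq.label,
        source_fps=seq.source_fps,
    )


def temporal_normalize(seq: FrameSequence, t_target: int) -> FrameSequence:
    """Resample the sequence to exactly `t_target` frames.

    Each pixel trajectory is interpolated piecewise-linearly at uniform
    fractional positions; the first and last frames are preserved exactly and
    all interpolation weights are convex, so per-pixel bounds are preserved.
    """
    if t_target < 2:
        raise ValueError(f"t_target must be >= 2, got {t_target}")
    t = seq.n_frames
    if t < 2:
        raise DegenerateInputError("temporal normalisation needs >= 2 frames")
    positions = np.linspace(0.0, t - 1, t_target)
    lo = np.floor(positions).astype(int)
    lo = np.minimum(lo, t - 2)
    w = (positions - lo)[:, None, None, None]
    frames = (1.0 - w) * seq.frames[lo] + w * seq.frames[lo + 1]
    # exact endpoints (and exact copies wherever the position is integral)
    integral = np.isclose(positions, np.round(positions))
    frames[integral] = seq.frames[np.round(positions[integral]).astype(int)]
    return FrameSequence(
        frames=frames, subject_id=seq.subject_id, sample_id=seq.sample_id,
        label=seq.label, source_fps=seq.source_fps,
    )


# ---------------------------------------------------------------------------
# Optical flow
# ---------------------------------------------------------------------------

def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.shape[-1] == 1:
        return frame[..., 0]
    if frame.shape[-1] == 3:
        return rgb2gray(frame)
    return frame.mean(axis=-1)


def _ilk(im0: np.ndarray, im1: np.ndarray) -> np.ndarray:
    v = optical_flow_ilk(im0, im1, radius=7)
    return np.stack([v[1], v[0]], axis=-1)  # (row, col) -> (x, y)


def _tvl1(im0: np.ndarray, im1: np.ndarray) -> np.ndarray:
    v = optical_flow_tvl1(im0, im1)
    return np.stack([v[1], v[0]], axis=-1)


FLOW_ESTIMATORS: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "ilk": _ilk,
    "tvl1": _tvl1,
}


def compute_optical_flow(seq: FrameSequence,
                         estimator: str | Callable = "ilk") -> FlowSequence:
    """Dense displacement from frame k to frame k+1 for every adjacent pair.

    Output flows[k] has shape (H, W, 2), last axis ordered (x, y), units of
    pixels at the current frame size. `estimator` is a registry name or a
    callable (gray0, gray1) -> (H, W, 2).
    """
    if seq.n_frames < 2:
        raise DegenerateInputError("optical flow needs >= 2 frames")
    fn = FLOW_ESTIMATORS[estimator] if isinstance(estimator, str) else estimator
    grays = [_to_gray(f) for f in seq.frames]
    fields = []
    for k in range(len(grays) - 1):
        try:
            fields.append(np.asarray(fn(grays[k], grays[k + 1]), dtype=np.float64))
        except Exception as exc:  # noqa: BLE001 - attach the pair index
            raise RuntimeError(f"flow estimation failed on frame pair {k}: {exc}") from exc
    return FlowSequence(
        flows=np.stack(fields), subject_id=seq.subject_id,
        sample_id=seq.sample_id, label=seq.label,
    )


def encode_flow(flows: np.ndarray, clip: float = FLOW_CLIP) -> np.ndarray:
    """Map displacement fields to bounded network inputs in [0, 1].

    Values are clipped to [-clip, clip] pixels and rescaled linearly;
    zero motion maps to 0.5. Micro-expression motion is sub-pixel to
    few-pixel, so the default +/-8 px bound is loose.
    """
    return (np.clip(flows, -clip, clip) + clip) / (2.0 * clip)
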