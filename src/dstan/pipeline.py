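"""Glue between raw sequences and the stream tensors.

Preprocessing is per-sample (no cross-sample statistics), so it is computed
once up front and folds simply index into the resulting tensors.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from dstan.data import SequenceDataset
from dstan.preprocess import (
    compute_optical_flow,
    encode_flow,
    spatial_normalize,
    temporal_normalize,
)
from dstan.streams import StreamDataset


def _to_gray_stack(frames: np.ndarray) -> np.ndarray:
    """(T, H, W, C) -> (T, 1, H, W) single-channel intensity."""
    if frames.shape[-1] == 1:
        gray = frames[..., 0]
    else:
        gray = frames @ np.array([0.2125, 0.7154, 0.0721])
    return gray[:, None, :, :]


def prepare_streams(dataset: SequenceDataset, t: int = 9,
                    frame_size: tuple[int, int] = (224, 224),
                    estimator: str | Callable = "ilk",
                    ) -> tuple[StreamDataset, StreamDataset]:
    """Normalise every sample and build (appearance, motion) stream tensors.

    Appearance: t grayscale frames. Motion: the t-1 adjacent-pair flow fields
    of the normalised sequence, clipped and rescaled to [0, 1] (no padding;
    the temporal model accepts either length).
    """
    app, mot = [], []
    y, sample_ids, subject_ids = [], [], []
    for seq in dataset.sequences:
        norm = temporal_normalize(spatial_normalize(seq, frame_size), t)
        app.append(_to_gray_stack(norm.frames))
        flow = compute_optical_flow(norm, estimator=estimator)
        mot.append(encode_flow(flow.flows).transpose(0, 3, 1, 2))
        y.append(seq.label)
        sample_ids.append(seq.sample_id)
        subject_ids.append(seq.subject_id)
    appearance = StreamDataset(np.stack(app), np.array(y), sample_ids, subject_ids)
    motion = StreamDataset(np.stack(mot), np.array(y), sample_ids, subject_ids)
    return appearance, motion


def subset_stream(ds: StreamDataset, sample_ids: list[str]) -> StreamDataset:
    wanted = set(sample_ids)
    idx = [i for i, sid in enumerate(ds.sample_ids) if sid in wanted]
    return StreamDataset(
        ds.x[idx], ds.y[idx],
        [ds.sample_ids[i] for i in idx],
        [ds.subject_ids[i] for i in idx],
    )
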