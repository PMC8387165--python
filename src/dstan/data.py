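"""Core containers: frame sequences, optical-flow sequences and labelled datasets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DegenerateInputError(ValueError):
    """Raised when an input violates a structural precondition (e.g. <2 frames)."""


@dataclass
class FrameSequence:
    """A stack of face frames for one micro-expression sample.

    frames has shape (T, H, W, C) with intensities in [0, 1]; grayscale inputs
    are carried with C=1.
    """

    frames: np.ndarray
    subject_id: str
    sample_id: str
    label: int
    source_fps: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim == 3:  # (T, H, W) -> (T, H, W, 1)
            self.frames = self.frames[..., None]
        if self.frames.ndim != 4:
            raise ValueError(f"frames must be (T, H, W, C), got {self.frames.shape}")
        t, h, w, _ = self.frames.shape
        if h < 8 or w < 8:
            raise DegenerateInputError(f"frames too small: {h}x{w} (need >= 8x8)")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")
        if self.frames.min() < -1e-9 or self.frames.max() > 1 + 1e-9:
            raise ValueError("frame intensities must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]


@dataclass
class FlowSequence:
    """Dense displacement fields between adjacent frames of one sample.

    flows has shape (T-1, H, W, 2); the last axis is (x, y) displacement in
    pixels at the normalised frame size, row-major with origin top-left.
    """

    flows: np.ndarray
    subject_id: str
    sample_id: str
    label: int

    def __post_init__(self) -> None:
        self.flows = np.asarray(self.flows, dtype=np.float64)
        if self.flows.ndim != 4 or self.flows.shape[-1] != 2:
            raise ValueError(f"flows must be (T-1, H, W, 2), got {self.flows.shape}")
        if not np.isfinite(self.flows).all():
            raise ValueError("flows contain non-finite values")

    @property
    def n_fields(self) -> int:
        return self.flows.shape[0]


@dataclass
class SequenceDataset:
    """A labelled, subject-structured collection of samples.

    `flows` is parallel to `sequences` when optical flow has been computed.
    """

    sequences: list[FrameSequence]
    flows: list[FlowSequence] | None = None
    class_names: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.sequences],
                "subject_id": [s.subject_id for s in self.sequences],
                "label": [s.label for s in self.sequences],
            }
        )

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.sequences})

    @property
    def classes(self) -> list[int]:
        return sorted({s.label for s in self.sequences})

    def subset(self, sample_ids: list[str]) -> "SequenceDataset":
        wanted = set(sample_ids)
        idx = [i for i, s in enumerate(self.sequences) if s.sample_id in wanted]
        return SequenceDataset(
            sequences=[self.sequences[i] for i in idx],
            flows=None if self.flows is None else [self.flows[i] for i in idx],
            class_names=dict(self.class_names),
        )
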