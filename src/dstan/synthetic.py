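"""Synthetic micro-expression generator.

Real micro-expression corpora (SMIC/CASME-style) are per-subject sets of
short clips in which a low-amplitude, spatially localised facial deformation
follows an onset-apex-offset arc on top of a stable identity. The generator
emulates exactly that structure: each subject is a smooth face-like intensity
template (elliptical head, eye/brow/mouth/nose blobs with per-identity
geometric jitter); each sample warps the template around one facial region
with a Gaussian-windowed translation whose magnitude follows a triangular
temporal profile (zero at both ends, maximal at the apex), plus optional
brightness change at the apex, small global drift and additive pixel noise.

The default three classes are complementary by design: one is mainly a
motion-direction cue at the mouth, one a motion-direction cue at the brows,
and one mainly a static appearance cue (brightness at the eyes with barely
any motion) — so the appearance and motion streams carry genuinely different
information, as in real data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from dstan.data import FrameSequence, SequenceDataset


@dataclass
class SubjectTemplate:
    """A per-subject face-like base image and its region geometry."""

    base_image: np.ndarray                       # (H, W) in [0, 1]
    region_centers: dict[str, tuple[float, float]]  # name -> (row, col)
    identity_seed: int


@dataclass
class MotionSpec:
    """How one class deforms a subject template."""

    class_label: int
    target_region: str
    displacement: tuple[float, float] = (2.0, 0.0)   # (dx, dy) px at apex
    intensity_shift: float = 0.0                     # brightness at apex
    amplitude_jitter: float = 0.1                    # relative std of apex amplitude
    noise_std: float = 0.01                          # additive pixel noise
    global_drift: float = 0.5                        # max per-sequence drift, px
    window_sigma: float = 6.0                        # Gaussian warp window, px

    def __post_init__(self) -> None:
        if float(np.hypot(*self.displacement)) > 8.0:
            raise ValueError("apex displacement magnitude must be <= 8 px")


@dataclass
class SyntheticDatasetSpec:
    """Shape and seeding of a full synthetic corpus."""

    n_subjects: int = 8
    motion_specs: list[MotionSpec] = field(default_factory=lambda: default_classes())
    sequences_per_class_per_subject: int = 6
    t: int = 9
    frame_size: int = 64
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sequences_per_class_per_subject < 1:
            raise ValueError("counts must be >= 1")
        if self.t < 2:
            raise ValueError("t must be >= 2")


def default_classes() -> list[MotionSpec]:
    """Three complementary classes mirroring a positive/negative/surprise arity."""
    return [
        MotionSpec(class_label=0, target_region="mouth", displacement=(2.5, 0.0)),
        MotionSpec(class_label=1, target_region="brows", displacement=(0.0, 2.5)),
        MotionSpec(class_label=2, target_region="eyes", displacement=(0.4, 0.0),
                   intensity_shift=0.30),
    ]


CLASS_NAMES = {0: "positive", 1: "negative", 2: "surprise"}


def _gaussian_blob(h: int, w: int, center: tuple[float, float], sigma: float
                   ) -> np.ndarray:
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    return np.exp(-(((rows - center[0]) ** 2) + ((cols - center[1]) ** 2))
                  / (2.0 * sigma**2))


def make_subject(identity_seed: int, size: int = 64) -> SubjectTemplate:
    """A smooth face-like template with seeded geometric jitter; deterministic."""
    rng = np.random.default_rng(identity_seed)
    h = w = size
    cy, cx = h / 2.0, w / 2.0
    ry, rx = 0.42 * h, 0.34 * w

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    ellipse = (((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2)
    head = np.clip(1.0 - ellipse, 0.0, 1.0) ** 0.5
    img = 0.15 + 0.55 * head

    jitter = lambda s: float(rng.uniform(-s, s))  # noqa: E731
    eye_dy = 0.12 * h
    eye_dx = 0.14 * w
    centers = {
        "left_eye": (cy - eye_dy + jitter(1.5), cx - eye_dx + jitter(1.5)),
        "right_eye": (cy - eye_dy + jitter(1.5), cx + eye_dx + jitter(1.5)),
        "left_brow": (cy - 0.20 * h + jitter(1.5), cx - eye_dx + jitter(1.5)),
        "right_brow": (cy - 0.20 * h + jitter(1.5), cx + eye_dx + jitter(1.5)),
        "nose": (cy + 0.04 * h + jitter(1.0), cx + jitter(1.0)),
        "mouth": (cy + 0.24 * h + jitter(1.5), cx + jitter(2.0)),
    }
    depth = {"left_eye": 0.35, "right_eye": 0.35, "left_brow": 0.25,
             "right_brow": 0.25, "nose": 0.15, "mouth": 0.30}
    sigma = {"left_eye": 0.035 * w, "right_eye": 0.035 * w, "left_brow": 0.04 * w,
             "right_brow": 0.04 * w, "nose": 0.03 * w, "mouth": 0.06 * w}
    for name, c in centers.items():
        img -= depth[name] * _gaussian_blob(h, w, c, sigma[name] + jitter(0.3))
    img += 0.02 * rng.standard_normal()  # per-identity global tone

    # composite centers used by the default classes
    centers["eyes"] = tuple(np.mean([centers["left_eye"], centers["right_eye"]], axis=0))
    centers["brows"] = tuple(np.mean([centers["left_brow"], centers["right_brow"]], axis=0))
    return SubjectTemplate(
        base_image=np.clip(img, 0.0, 1.0),
        region_centers={k: (float(v[0]), float(v[1])) for k, v in centers.items()},
        identity_seed=int(identity_seed),
    )


def triangular_profile(t: int, apex: int | None = None) -> np.ndarray:
    """Onset-apex-offset weights: zero endpoints, single maximum 1 at the apex.

    The default apex is the middle frame (index t//2). A profile needs t >= 3
    to be non-degenerate; for t == 2 the all-zero profile is returned.
    """
    if t < 3:
        return np.zeros(t)
    if apex is None:
        apex = t // 2
    apex = int(np.clip(apex, 1, t - 2))
    profile = np.empty(t)
    for k in range(t):
        profile[k] = k / apex if k <= apex else (t - 1 - k) / (t - 1 - apex)
    return profile


def _warp(image: np.ndarray, displacement: np.ndarray, window: np.ndarray
          ) -> np.ndarray:
    """Backward-map `image` by a Gaussian-windowed translation (bilinear)."""
    h, w = image.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dx, dy = displacement
    src_rows = rows - dy * window
    src_cols = cols - dx * window
    return map_coordinates(image, [src_rows, src_cols], order=1, mode="nearest")


def make_sequence(subject: SubjectTemplate, spec: MotionSpec, t: int,
                  seed: int, subject_id: str = "S00", sample_id: str = "s000"
                  ) -> FrameSequence:
    """One synthetic clip: template + profiled local warp + drift + noise."""
    if spec.target_region not in subject.region_centers:
        raise ValueError(
            f"unknown region {spec.target_region!r}; template has "
            f"{sorted(subject.region_centers)}"
        )
    rng = np.random.default_rng(seed)
    h, w = subject.base_image.shape
    center = subject.region_centers[spec.target_region]
    window = _gaussian_blob(h, w, center, spec.window_sigma)
    profile = triangular_profile(t)
    amp = 1.0 + (spec.amplitude_jitter * rng.standard_normal()
                 if spec.amplitude_jitter > 0 else 0.0)
    amp = max(amp, 0.2)
    drift_dir = rng.uniform(-1.0, 1.0, size=2)
    norm = np.linalg.norm(drift_dir)
    drift_dir = drift_dir / norm if norm > 0 else np.array([1.0, 0.0])
    drift_mag = rng.uniform(0.0, spec.global_drift)
    disp = np.asarray(spec.displacement, dtype=float)

    frames = np.empty((t, h, w), dtype=np.float64)
    ones = np.ones_like(window)
    for k in range(t):
        frame = subject.base_image
        local = amp * profile[k] * disp
        if np.any(local != 0.0):
            frame = _warp(frame, local, window)
        drift = drift_mag * drift_dir * (k / max(t - 1, 1))
        if drift_mag > 0:
            frame = _warp(frame, drift, ones)
        if spec.intensity_shift != 0.0:
            frame = frame + spec.intensity_shift * amp * profile[k] * window
        if spec.noise_std > 0:
            frame = frame + spec.noise_std * rng.standard_normal((h, w))
        frames[k] = np.clip(frame, 0.0, 1.0)
    return FrameSequence(frames=frames[..., None], subject_id=subject_id,
                         sample_id=sample_id, label=spec.class_label)


def subject_templates(spec: SyntheticDatasetSpec) -> dict[str, SubjectTemplate]:
    """The per-subject templates a dataset spec generates, keyed by subject id."""
    root = np.random.SeedSequence(spec.master_seed)
    subject_seeds, _ = root.spawn(2)
    seeds = subject_seeds.generate_state(spec.n_subjects)
    return {
        f"S{si:02d}": make_subject(int(seeds[si] % (2**31)), size=spec.frame_size)
        for si in range(spec.n_subjects)
    }


def make_dataset(spec: SyntheticDatasetSpec) -> SequenceDataset:
    """The full corpus: n_subjects x classes x sequences_per_class_per_subject."""
    root = np.random.SeedSequence(spec.master_seed)
    _, sample_seed_root = root.spawn(2)
    templates = subject_templates(spec)
    sequences = []
    counter = 0
    sample_rngs = sample_seed_root.generate_state(
        spec.n_subjects * len(spec.motion_specs) * spec.sequences_per_class_per_subject
    )
    for si in range(spec.n_subjects):
        subject_id = f"S{si:02d}"
        subject = templates[subject_id]
        for mspec in spec.motion_specs:
            for rep in range(spec.sequences_per_class_per_subject):
                sample_id = f"{subject_id}_c{mspec.class_label}_r{rep:02d}"
                seq = make_sequence(
                    subject, mspec, spec.t,
                    seed=int(sample_rngs[counter] % (2**31)),
                    subject_id=subject_id, sample_id=sample_id,
                )
                sequences.append(seq)
                counter += 1
    names = {m.class_label: CLASS_NAMES.get(m.class_label, str(m.class_label))
             for m in spec.motion_specs}
    return SequenceDataset(sequences=sequences, class_names=names)


def zero_amplitude(spec: SyntheticDatasetSpec) -> SyntheticDatasetSpec:
    """Negative-control variant: identical structure, no class signal at all."""
    specs = [
        replace(m, displacement=(0.0, 0.0), intensity_shift=0.0)
        for m in spec.motion_specs
    ]
    return replace(spec, motion_specs=specs)


# ---------------------------------------------------------------------------
# On-disk layout (what the preprocess module reads back)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SequenceDataset, root: str | os.PathLike) -> Path:
    """Write frame directories plus labels.csv; returns the labels path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in dataset.sequences:
        sample_dir = root / seq.sample_id
        sample_dir.mkdir(exist_ok=True)
        for k in range(seq.n_frames):
            frame8 = np.round(seq.frames[k, :, :, 0] * 255.0).astype(np.uint8)
            iio.imwrite(sample_dir / f"frame_{k:03d}.png", frame8)
        rows.append(
            {"sample_id": seq.sample_id, "subject_id": seq.subject_id,
             "label": seq.label, "path": str(sample_dir)}
        )
    labels = root / "labels.csv"
    pd.DataFrame(rows).to_csv(labels, index=False)
    return labels
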