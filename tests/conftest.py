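import numpy as np
import pytest

from dstan.streams import StreamConfig
from dstan.synthetic import SyntheticDatasetSpec, make_dataset


def tiny_config(**overrides) -> StreamConfig:
    """A config small enough for oracle and gradient tests (32x32 frames)."""
    base = dict(
        input_channels=1, conv_widths=(4, 4, 8, 8, 16), lstm_hidden=8,
        num_classes=3, ratio=4, t=3, frame_size=(32, 32),
        learning_rate=1e-3, epochs=0, batch_size=4, seed=0,
    )
    base.update(overrides)
    return StreamConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """3 subjects x 3 classes x 2 sequences at 32x32 — pipeline-level fixture."""
    spec = SyntheticDatasetSpec(
        n_subjects=3, sequences_per_class_per_subject=2, t=9, frame_size=32,
        master_seed=7,
    )
    return make_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
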