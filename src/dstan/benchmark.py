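"""The bundled synthetic LOSOCV benchmark.

One canonical desk-scale configuration exercises the entire method: 8
subjects x 3 classes x 6 sequences of 9 frames at 64x64, reduced convolution
widths (8, 16, 32, 64, 64), LSTM width 64, Adam with learning rate 2e-3
(10 epochs for the appearance stream, 6 for the faster-converging motion
stream), batch size 16. The negative control re-runs the identical pipeline
on a zero-amplitude corpus (no class signal at all), where accuracy must sit
at chance.
"""

from __future__ import annotations

from dstan.evaluation import LosocvResult, run_losocv
from dstan.streams import StreamConfig
from dstan.synthetic import SyntheticDatasetSpec, make_dataset, zero_amplitude

FRAME_SIZE = 64
T_FRAMES = 9


def benchmark_spec(master_seed: int = 0, n_subjects: int = 8,
                   sequences_per_class: int = 6,
                   frame_size: int = FRAME_SIZE) -> SyntheticDatasetSpec:
    return SyntheticDatasetSpec(
        n_subjects=n_subjects,
        sequences_per_class_per_subject=sequences_per_class,
        t=T_FRAMES, frame_size=frame_size, master_seed=master_seed,
    )


def stream_configs(seed: int = 0, frame_size: int = FRAME_SIZE,
                   stan_epochs: int = 10, stmn_epochs: int = 6,
                   ) -> tuple[StreamConfig, StreamConfig]:
    """Benchmark-scale configs for (appearance, motion)."""
    common = dict(
        conv_widths=(8, 16, 32, 64, 64), lstm_hidden=64, num_classes=3,
        ratio=16, t=T_FRAMES, frame_size=(frame_size, frame_size),
        learning_rate=2e-3, batch_size=16, seed=seed,
    )
    stan = StreamConfig(input_channels=1, epochs=stan_epochs, **common)
    stmn = StreamConfig(input_channels=2, epochs=stmn_epochs, **common)
    return stan, stmn


def run_benchmark(master_seed: int = 0, negative_control: bool = False,
                  n_subjects: int = 8, sequences_per_class: int = 6,
                  frame_size: int = FRAME_SIZE,
                  stan_epochs: int = 10, stmn_epochs: int = 6) -> LosocvResult:
    """Generate the corpus and run the full dual-stream LOSOCV pipeline."""
    spec = benchmark_spec(master_seed, n_subjects, sequences_per_class, frame_size)
    if negative_control:
        spec = zero_amplitude(spec)
        # no signal to fit: a short schedule suffices for a chance-level model
        stan_epochs = min(stan_epochs, 3)
        stmn_epochs = min(stmn_epochs, 3)
    dataset = make_dataset(spec)
    stan, stmn = stream_configs(master_seed, frame_size, stan_epochs, stmn_epochs)
    return run_losocv(dataset, stan, stmn, t=T_FRAMES,
                      frame_size=(frame_size, frame_size))
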