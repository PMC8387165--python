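"""Stream forwards against layer-by-layer oracles, training and checkpoints."""

import numpy as np
import pytest

import _oracles as oracle
from conftest import tiny_config
from dstan.data import DegenerateInputError
from dstan.streams import (
    StreamConfig,
    StreamDataset,
    build_stream,
    extract_stream_features,
    load_stream,
    save_stream,
    stan_spatial_forward,
    stmn_spatial_forward,
    temporal_forward,
    train_stream,
)


def _train_briefly(kind, channels, rng, epochs=1, **overrides):
    """A model whose BN running stats are non-trivial (one short training run)."""
    cfg = tiny_config(input_channels=channels, epochs=epochs, **overrides)
    x = rng.random((6, cfg.t, channels, 32, 32)).astype(np.float32)
    y = np.array([0, 1, 2, 0, 1, 2])
    ds = StreamDataset(x, y, [f"s{i}" for i in range(6)], ["A"] * 6)
    return train_stream(ds, cfg, kind), ds


class TestSpatialForwards:
    @pytest.mark.parametrize("kind,channels", [("appearance", 1), ("motion", 2)])
    def test_matches_layer_by_layer_oracle(self, kind, channels, rng):
        model, _ = _train_briefly(kind, channels, rng)
        model.net.astype(np.float64)
        fwd = stan_spatial_forward if kind == "appearance" else stmn_spatial_forward
        for trial in range(3):
            frame = np.random.default_rng(trial).random((channels, 32, 32))
            got = fwd(frame, model)
            expected = oracle.stream_frame_forward_oracle(model.net, frame)
            np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_feature_dimensions(self, rng):
        stan = build_stream(tiny_config(), "appearance")
        stmn = build_stream(tiny_config(input_channels=2), "motion")
        f_a = stan_spatial_forward(np.zeros((1, 32, 32)), stan)
        f_m = stmn_spatial_forward(np.zeros((2, 32, 32)), stmn)
        widths = stan.config.conv_widths
        assert f_a.shape == (widths[2] + widths[4],)  # low || high concatenation
        assert f_m.shape == (widths[4],)

    def test_zero_input_zero_bias_gives_zero_feature(self):
        model = build_stream(tiny_config(), "appearance")
        for conv in (*model.net.convs, model.net.low_conv, model.net.high_conv):
            conv.bias.data[:] = 0.0
        feat = stan_spatial_forward(np.zeros((1, 32, 32)), model)
        np.testing.assert_allclose(feat, 0.0, atol=1e-7)

    def test_wrong_frame_size_rejected(self):
        model = build_stream(tiny_config(), "appearance")
        with pytest.raises(ValueError, match="divisible by 32"):
            stan_spatial_forward(np.zeros((1, 30, 30)), model)

    def test_kind_mismatch_rejected(self):
        model = build_stream(tiny_config(), "appearance")
        with pytest.raises(ValueError):
            stmn_spatial_forward(np.zeros((2, 32, 32)), model)


class TestTemporalForward:
    def test_sequence_feature_is_mean_of_step_outputs(self, rng):
        model = build_stream(tiny_config(), "appearance")
        feats = rng.random((9, model.feature_dim)).astype(np.float32)
        out = temporal_forward(feats, model)
        np.testing.assert_allclose(out.vector, out.step_outputs.mean(axis=0),
                                   atol=1e-6)
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(out.probabilities >= 0)

    def test_single_frame_mean_is_identity(self, rng):
        model = build_stream(tiny_config(), "appearance")
        feats = rng.random((1, model.feature_dim)).astype(np.float32)
        out = temporal_forward(feats, model)
        np.testing.assert_array_equal(out.vector, out.step_outputs[0])

    def test_empty_sequence_rejected(self):
        model = build_stream(tiny_config(), "appearance")
        with pytest.raises(DegenerateInputError):
            temporal_forward(np.zeros((0, model.feature_dim)), model)

    def test_matches_full_sequence_oracle(self, rng):
        model, _ = _train_briefly("motion", 2, rng)
        model.net.astype(np.float64)
        frames = np.random.default_rng(11).random((3, 2, 32, 32))
        expected = oracle.sequence_forward_oracle(model, frames)
        feats = np.stack([stmn_spatial_forward(f, model) for f in frames])
        got = temporal_forward(feats, model)
        np.testing.assert_allclose(got.vector, expected["f"], atol=1e-4)
        np.testing.assert_allclose(got.probabilities, expected["proba"], atol=1e-4)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        cfg = tiny_config(num_classes=2, epochs=12, learning_rate=2e-3, seed=2)
        x = np.zeros((8, 3, 1, 32, 32), dtype=np.float32)
        x[:4, :, :, 4:14, 4:14] = 1.0   # class 0: bright top-left block
        x[4:, :, :, 18:28, 18:28] = 1.0  # class 1: bright bottom-right block
        x += 0.05 * rng.random(x.shape).astype(np.float32)
        x = np.clip(x, 0, 1)
        y = np.array([0] * 4 + [1] * 4)
        ds = StreamDataset(x, y, [f"s{i}" for i in range(8)], ["A"] * 8)
        model = train_stream(ds, cfg, "appearance")
        assert model.training_log[-1] < model.training_log[0]

    def test_zero_epochs_returns_initialized_model(self, rng):
        model, _ = _train_briefly("appearance", 1, rng, epochs=0)
        assert model.training_log == []

    def test_single_class_rejected(self, rng):
        cfg = tiny_config(epochs=1)
        x = rng.random((4, 3, 1, 32, 32)).astype(np.float32)
        ds = StreamDataset(x, np.zeros(4, dtype=int), list("abcd"), ["A"] * 4)
        with pytest.raises(ValueError, match="classes"):
            train_stream(ds, cfg, "appearance")


class TestExtraction:
    def test_eval_mode_determinism_and_order(self, rng):
        model, ds = _train_briefly("appearance", 1, rng)
        f1 = extract_stream_features(model, ds)
        f2 = extract_stream_features(model, ds)
        np.testing.assert_array_equal(f1.features, f2.features)
        assert f1.sample_ids == ds.sample_ids
        assert len(f1.features) == len(ds)

    def test_composition_with_manual_per_frame_path(self, rng):
        model, ds = _train_briefly("appearance", 1, rng)
        table = extract_stream_features(model, ds)
        k = 2
        feats = np.stack([stan_spatial_forward(f, model) for f in ds.x[k]])
        manual = temporal_forward(feats, model)
        np.testing.assert_allclose(table.features[k], manual.vector, atol=1e-4)

    def test_frame_size_mismatch_rejected(self, rng):
        model, _ = _train_briefly("appearance", 1, rng)
        bad = StreamDataset(np.zeros((2, 3, 1, 64, 64), dtype=np.float32),
                            np.array([0, 1]), ["a", "b"], ["A", "A"])
        with pytest.raises(ValueError, match="frame size"):
            extract_stream_features(model, bad)


class TestAblationAndCheckpoints:
    def test_attention_free_path_runs_and_differs(self, rng):
        plain_cfg = tiny_config(use_spatial_attention=False,
                                use_channel_attention=False,
                                use_temporal_attention=False, use_lhfn=False)
        attended, ds = _train_briefly("appearance", 1, rng, epochs=0)
        plain = build_stream(plain_cfg, "appearance")
        fa = extract_stream_features(attended, ds)
        fp = extract_stream_features(plain, ds)
        assert fa.features.shape[1] != fp.features.shape[1] or not np.allclose(
            fa.features, fp.features)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        model, ds = _train_briefly("motion", 2, rng)
        path = tmp_path / "stmn.npz"
        save_stream(model, path)
        loaded = load_stream(path)
        f1 = extract_stream_features(model, ds)
        f2 = extract_stream_features(loaded, ds)
        np.testing.assert_array_equal(f1.features, f2.features)
        assert loaded.training_log == model.training_log


def test_config_validation():
    with pytest.raises(ValueError, match="divisible by 32"):
        StreamConfig(frame_size=(60, 60))
    with pytest.raises(ValueError, match="ratio"):
        StreamConfig(conv_widths=(8, 16, 32, 64, 50), ratio=16,
                     frame_size=(64, 64))
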