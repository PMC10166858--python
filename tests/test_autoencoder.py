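import numpy as np
import pytest

from lsuss import (TimeSeries, TrainingConfig, build_autoencoder, encode_all,
                   train_autoencoder)
from lsuss.autoencoder import TrainedAutoencoder, _build_networks


class TestBuildSpec:
    def test_fully_connected_sizes_and_ratio(self):
        spec = build_autoencoder("fully_connected", 9, 50)
        assert spec.latent_dim == 45  # 0.1 * 450
        assert "450->225" in spec.layer_plan[0]
        assert "225->112" in spec.layer_plan[1]
        assert "112->45" in spec.layer_plan[2]

    def test_convolutional_latent_ratio(self):
        assert build_autoencoder("convolutional", 10, 24).latent_dim == 40  # 240/6

    def test_fully_connected_minimum_latent(self):
        assert build_autoencoder("fully_connected", 1, 10).latent_dim == 1

    @pytest.mark.parametrize("kind,nc,nw,msg", [
        ("convolutional", 3, 18, "divisible by 4"),
        ("fully_connected", 1, 8, ">= 10"),
        ("nonsense", 1, 16, "unknown"),
    ])
    def test_invalid_specs_rejected_with_hint(self, kind, nc, nw, msg):
        with pytest.raises(ValueError, match=msg):
            build_autoencoder(kind, nc, nw)

    @pytest.mark.parametrize("kind,ratio", [("fully_connected", 0.1),
                                            ("convolutional", 1 / 6)])
    def test_bottleneck_ratio_within_rounding(self, kind, ratio):
        for nc, nw in [(2, 16), (4, 32), (10, 32), (8, 64)]:
            spec = build_autoencoder(kind, nc, nw)
            d = nc * nw
            assert abs(spec.latent_dim - ratio * d) <= 0.5 + 1e-9

    def test_conv_parameter_count_matches_hand_count(self):
        nc, nw = 2, 16
        spec = build_autoencoder("convolutional", nc, nw)
        enc, dec = _build_networks(spec, np.random.default_rng(0))
        d, lat = nc * nw, spec.latent_dim
        conv = (2 * nc * nc * 3 + 2 * nc) + (4 * nc * 2 * nc * 3 + 4 * nc)
        dense = (d * d // 2 + d // 2) + (d // 2 * d // 4 + d // 4) \
            + (d // 4 * lat + lat)
        tied_biases = d // 4 + d // 2 + d
        convT = (4 * nc * 2 * nc * 3 + 2 * nc) + (2 * nc * nc * 3 + nc)
        model = TrainedAutoencoder(spec, enc, dec, {"kind": "none"},
                                   TrainingConfig())
        assert model.n_params == conv + dense + tied_biases + convT


def _mixture_ts(n=1500, nc=4, noise=0.01, seed=0):
    """Channels are a fixed linear mixture of 2 sinusoid sources + noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    src = np.stack([np.sin(2 * np.pi * 0.031 * t),
                    np.sin(2 * np.pi * 0.093 * t + 1.0)])
    mix = rng.normal(size=(nc, 2))
    return TimeSeries((mix @ src).T + noise * rng.normal(size=(n, nc)))


class TestTraining:
    def test_same_seed_bitwise_identical(self):
        ts = _mixture_ts(400)
        spec = build_autoencoder("fully_connected", 4, 16)
        cfg = TrainingConfig(seed=11, max_epochs=3, patience=2, train_stride=4)
        m1, h1 = train_autoencoder(spec, ts, cfg)
        m2, h2 = train_autoencoder(spec, ts, cfg)
        assert h1["val"] == h2["val"]
        for a, b in zip(m1.encoder.params, m2.encoder.params):
            np.testing.assert_array_equal(a.value, b.value)

    def test_low_rank_mixture_is_reconstructible(self):
        # latent >= number of sources, so validation MSE should land far
        # below the variance of the standardized input (which is 1)
        ts = _mixture_ts()
        spec = build_autoencoder("fully_connected", 4, 16)
        cfg = TrainingConfig(seed=0, max_epochs=300, patience=60, train_stride=2)
        model, hist = train_autoencoder(spec, ts, cfg)
        assert min(hist["val"]) < 0.1

    def test_constant_zero_series_trivially_reconstructed(self):
        ts = TimeSeries(np.zeros((300, 2)))
        spec = build_autoencoder("fully_connected", 2, 8)
        cfg = TrainingConfig(seed=0, max_epochs=200, patience=200,
                             scaler="none", train_stride=2)
        model, hist = train_autoencoder(spec, ts, cfg)
        assert min(hist["val"]) < 1e-4

    def test_best_val_history_monotone(self):
        ts = _mixture_ts(500)
        spec = build_autoencoder("fully_connected", 4, 16)
        model, hist = train_autoencoder(
            spec, ts, TrainingConfig(seed=2, max_epochs=8, patience=8,
                                     train_stride=4))
        assert np.all(np.diff(hist["best_val"]) <= 0)

    def test_beats_constant_predictor_on_validation(self):
        ts = _mixture_ts(600, seed=5)
        spec = build_autoencoder("fully_connected", 4, 16)
        cfg = TrainingConfig(seed=3, max_epochs=150, patience=40, train_stride=3)
        model, hist = train_autoencoder(spec, ts, cfg)
        # the best constant predictor's MSE is the (scaled) data variance
        windows = np.lib.stride_tricks.sliding_window_view(
            ts.values, 16, axis=0).transpose(0, 2, 1)[::3]
        X = model._prep(windows)
        const_mse = float(np.mean((X - X.mean(axis=0)) ** 2))
        assert min(hist["val"]) <= const_mse + 1e-6

    def test_too_few_windows_rejected(self):
        ts = TimeSeries(np.zeros((16, 2)))
        spec = build_autoencoder("fully_connected", 2, 16)
        with pytest.raises(ValueError, match="split"):
            train_autoencoder(spec, ts, TrainingConfig(max_epochs=1))

    def test_channel_mismatch_rejected(self):
        spec = build_autoencoder("fully_connected", 3, 16)
        with pytest.raises(ValueError, match="channels"):
            train_autoencoder(spec, _mixture_ts(nc=4), TrainingConfig())


class TestEncodeAll:
    @pytest.fixture(scope="class")
    def small_model(self):
        spec = build_autoencoder("fully_connected", 2, 20)
        cfg = TrainingConfig(seed=0, max_epochs=2, patience=1, train_stride=5)
        model, _ = train_autoencoder(spec, _mixture_ts(400, nc=2), cfg)
        return model

    def test_row_count(self, small_model):
        ts = _mixture_ts(100, nc=2, seed=9)
        assert len(encode_all(small_model, ts, 20)) == 81

    def test_duplicate_windows_encode_identically(self, small_model):
        v = np.random.default_rng(3).normal(size=(60, 2))
        v[30:50] = v[5:25]
        F = encode_all(small_model, TimeSeries(v), 20).F
        np.testing.assert_array_equal(F[5], F[30])

    def test_encoding_is_deterministic(self, small_model):
        ts = _mixture_ts(90, nc=2, seed=4)
        np.testing.assert_array_equal(encode_all(small_model, ts, 20).F,
                                      encode_all(small_model, ts, 20).F)

    def test_shape_mismatches_rejected(self, small_model):
        with pytest.raises(ValueError, match="NW"):
            encode_all(small_model, _mixture_ts(90, nc=2), 16)
        with pytest.raises(ValueError, match="channels"):
            encode_all(small_model, _mixture_ts(90, nc=4), 20)

    def test_save_load_round_trip(self, small_model, tmp_path):
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = TrainedAutoencoder.load(path)
        ts = _mixture_ts(80, nc=2, seed=6)
        np.testing.assert_array_equal(encode_all(loaded, ts, 20).F,
                                      encode_all(small_model, ts, 20).F)
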