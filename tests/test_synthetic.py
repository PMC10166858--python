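import numpy as np
import pytest
from scipy.signal import periodogram

from lsuss import (RegimeSpec, SourceSpec, generate_discontinuous_training_set,
                   generate_regime_series)
from lsuss.synthetic import emg_like_dataset, emg_like_regimes


def _two_regimes(dur=(300, 400)):
    return [
        RegimeSpec("slow", (SourceSpec("sinusoid", {"frequency": 0.03}),
                            SourceSpec("ar", {"coefficients": [0.6]})), dur),
        RegimeSpec("fast", (SourceSpec("sinusoid", {"frequency": 0.2}),
                            SourceSpec("ar", {"coefficients": [0.9]})), dur),
    ]


class TestGenerateRegimeSeries:
    def test_single_segment_has_no_changepoints(self):
        ds = generate_regime_series(_two_regimes(), 1, nc=4, n_sources=2,
                                    noise_sd=0.1, seed=0)
        assert len(ds.gt) == 0

    def test_five_segments_have_four_boundaries(self):
        ds = generate_regime_series(_two_regimes(), 5, nc=4, n_sources=2,
                                    noise_sd=0.1, repeat_regimes=True, seed=1)
        assert len(ds.gt) == 4
        assert np.all(np.diff(ds.gt.indices) > 0)

    def test_boundaries_are_exact_segment_edges(self):
        ds = generate_regime_series(_two_regimes((100, 100)), 3, nc=3,
                                    n_sources=2, noise_sd=0.0,
                                    repeat_regimes=True, seed=2)
        np.testing.assert_array_equal(ds.gt.indices, [100, 200])

    def test_same_seed_is_bitwise_identical(self):
        a = generate_regime_series(_two_regimes(), 4, nc=4, n_sources=2,
                                   noise_sd=0.2, repeat_regimes=True, seed=7)
        b = generate_regime_series(_two_regimes(), 4, nc=4, n_sources=2,
                                   noise_sd=0.2, repeat_regimes=True, seed=7)
        np.testing.assert_array_equal(a.ts.values, b.ts.values)
        np.testing.assert_array_equal(a.gt.indices, b.gt.indices)

    def test_no_adjacent_repeats_in_repeat_mode(self):
        ds = generate_regime_series(_two_regimes(), 10, nc=3, n_sources=2,
                                    noise_sd=0.1, repeat_regimes=True, seed=3)
        seq = ds.regime_sequence
        assert all(seq[i] != seq[i + 1] for i in range(len(seq) - 1))

    def test_noiseless_observed_block_has_source_rank(self):
        ds = generate_regime_series(_two_regimes(), 2, nc=6, n_sources=2,
                                    noise_sd=0.0, repeat_regimes=True, seed=4)
        rank = np.linalg.matrix_rank(ds.ts.values, tol=1e-8)
        assert rank == 2

    def test_duration_guidance_enforced_when_nw_given(self):
        with pytest.raises(ValueError, match="3\\*NW"):
            generate_regime_series(_two_regimes((100, 120)), 2, nc=3,
                                   n_sources=2, noise_sd=0.1,
                                   repeat_regimes=True, seed=0, min_nw=50)

    def test_distinguishability_decays_with_noise(self):
        # spectral window descriptors separate disjoint-frequency regimes by
        # a wide margin in the noiseless limit; the margin decays with noise
        regimes = [
            RegimeSpec("slow", (SourceSpec("sinusoid", {"frequency": 0.03}),),
                       (400, 400)),
            RegimeSpec("fast", (SourceSpec("sinusoid", {"frequency": 0.2}),),
                       (400, 400)),
        ]

        def factor(noise):
            ds = generate_regime_series(regimes, 2, nc=5, n_sources=1,
                                        noise_sd=noise, repeat_regimes=True,
                                        seed=5)
            v, w = ds.ts.values, 64
            starts = [s for s in range(0, 800 - w, 16)
                      if s + w <= 400 or s >= 400]  # skip boundary straddlers
            feats = np.stack([periodogram(v[s:s + w], axis=0)[1].ravel()
                              for s in starts])
            labels = np.array([s >= 400 for s in starts])
            within, between = [], []
            for a in range(len(feats)):
                for b in range(a + 1, len(feats)):
                    d = np.linalg.norm(feats[a] - feats[b])
                    (within if labels[a] == labels[b] else between).append(d)
            return np.mean(between) / np.mean(within)

        factors = [factor(nz) for nz in (0.0, 0.5, 2.0)]
        assert factors[0] >= 5.0
        assert factors[0] > factors[1] > factors[2]


class TestDiscontinuousTrainingSet:
    def test_clip_count(self):
        clips = generate_discontinuous_training_set(
            _two_regimes(), reps=4, nc=3, n_sources=2, noise_sd=0.1, seed=0)
        assert len(clips) == 8  # 4 reps x 2 regimes

    def test_concatenation_boundary_count(self):
        clips = generate_discontinuous_training_set(
            _two_regimes(), reps=2, nc=3, n_sources=2, noise_sd=0.1, seed=1)
        boundaries = np.cumsum([c.n for c in clips])[:-1]
        assert len(boundaries) == len(clips) - 1

    def test_dominant_frequency_matches_regime_spec(self):
        regimes = [RegimeSpec("pure", (SourceSpec("sinusoid",
                                                  {"frequency": 0.11}),),
                              (1000, 1000))]
        clips = generate_discontinuous_training_set(
            regimes, reps=1, nc=2, n_sources=1, noise_sd=0.01, seed=2)
        f, pxx = periodogram(clips[0].values[:, 0])
        assert f[np.argmax(pxx)] == pytest.approx(0.11, abs=0.005)


class TestEmgLikeFixture:
    def test_default_conditions(self):
        ds = emg_like_dataset(seed=0)
        assert ds.ts.n_channels == 10
        assert len(ds.gt) == 4
        assert 5 * 1200 <= ds.ts.n <= 5 * 2000

    def test_regime_bank_has_disjoint_frequencies(self):
        regimes = emg_like_regimes()
        freqs = [r.sources[0].params["frequency"] for r in regimes]
        assert len(set(freqs)) == len(freqs)
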