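import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsuss import lrea, ltea, rea, scale_cac
from _oracles import rolling_stats_loop


def _valley_curve(L, valleys):
    """A flat curve at 1 with V-shaped valleys: {pos: depth}."""
    v = np.ones(L)
    for pos, depth in valleys.items():
        for off in range(-5, 6):
            if 0 <= pos + off < L:
                v[pos + off] = min(v[pos + off], depth + 0.05 * abs(off))
    return v


class TestRea:
    def test_single_valley(self):
        cac = _valley_curve(100, {40: 0.0})
        assert list(rea(cac, 1, 10).indices) == [40]

    def test_exclusion_skips_nearby_valley(self):
        # two valleys 10 apart; with excl 15 the shallower one is masked
        # and the next pick lands at the third valley far away
        cac = _valley_curve(200, {50: 0.0, 60: 0.1, 150: 0.3})
        got = list(rea(cac, 2, 15).indices)
        assert got == [50, 150]

    def test_three_valleys_recovered_sorted(self):
        cac = _valley_curve(300, {250: 0.1, 40: 0.0, 150: 0.2})
        assert list(rea(cac, 3, 20).indices) == [40, 150, 250]

    def test_warns_when_not_enough_valleys(self):
        with pytest.warns(UserWarning, match="admissible"):
            got = rea(np.ones(10), 3, 20)
        assert len(got) == 1  # everything masked after the first pick

    def test_pairwise_gaps_exceed_exclusion(self):
        rng = np.random.default_rng(0)
        cac = rng.random(500)
        got = rea(cac, 8, 30).indices
        assert np.all(np.diff(got) > 30)


class TestScaleCac:
    def test_constant_curve_maps_to_zeros(self):
        out = scale_cac(np.full(50, 0.7), 5)
        np.testing.assert_array_equal(out.values, np.zeros(50))

    def test_saturated_window_equals_global_zscore(self):
        v = np.random.default_rng(1).random(40)
        out = scale_cac(v, 100, "centered")
        np.testing.assert_allclose(out.values, (v - v.mean()) / v.std(),
                                   atol=1e-10)

    @pytest.mark.parametrize("mode", ["centered", "trailing"])
    def test_matches_rolling_loop(self, mode):
        v = np.random.default_rng(2).random(300)
        out = scale_cac(v, 25, mode)
        mu, sd = rolling_stats_loop(v, 25, mode)
        np.testing.assert_allclose(out.mu_rolling, mu, atol=1e-10)
        np.testing.assert_allclose(out.sigma_rolling, sd, atol=1e-10)
        expect = np.where(sd >= 1e-12, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        np.testing.assert_allclose(out.values, expect, atol=1e-10)

    def test_trailing_uses_no_future_values(self):
        v = np.random.default_rng(3).random(200)
        a = scale_cac(v, 20, "trailing").values
        v2 = v.copy()
        v2[150:] = 9.9  # perturb the future
        b = scale_cac(v2, 20, "trailing").values
        np.testing.assert_array_equal(a[:150], b[:150])


class TestLrea:
    def test_prefers_locally_sharp_valley_over_global_plateau(self):
        # a long low plateau (globally lowest) vs a sharp dip in a high region
        v = np.ones(400)
        v[50:150] = 0.2             # plateau: low but locally flat
        v[299] = 0.45
        v[300] = 0.3                # sharp local valley
        v[301] = 0.45
        plain = rea(v, 1, 20)
        local = lrea(v, 1, 40, 20)
        assert 50 <= plain.indices[0] <= 150
        assert local.indices[0] == 300

    def test_single_valley(self):
        cac = _valley_curve(150, {70: 0.0})
        assert list(lrea(cac, 1, 30, 10).indices) == [70]

    def test_converges_to_rea_with_saturated_window(self):
        v = np.random.default_rng(4).random(120)
        saturated = lrea(v, 4, 10 * len(v), 10)
        global_z = rea((v - v.mean()) / v.std(), 4, 10)
        np.testing.assert_array_equal(saturated.indices, global_z.indices)


class TestLtea:
    def test_nothing_below_threshold_gives_empty_set(self):
        got = ltea(np.ones(100), 10, threshold=-1.0)
        assert len(got) == 0

    def test_single_run_reports_its_minimum(self):
        v = np.ones(1000)
        v[800:825] = 0.0
        v[812] = -0.5
        got = ltea(v, 50, threshold=-1.0, excl_width=30)
        assert list(got.indices) == [812]

    def test_threshold_and_exclusion_invariants_fuzzed(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            v = rng.random(400)
            got = ltea(v, 30, threshold=-1.0, excl_width=25)
            scaled = scale_cac(v, 30, "centered").values
            assert np.all(scaled[got.indices] <= -1.0)
            if len(got) > 1:
                assert np.all(np.diff(got.indices) > 25)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_deeper_valley_wins_exclusion_conflicts(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.random(300)
        got = ltea(v, 25, threshold=-0.8, excl_width=40)
        scaled = scale_cac(v, 25, "centered").values
        for pos in got.indices:
            # no strictly deeper sub-threshold valley minimum was discarded
            # within the exclusion radius of an accepted shallower one
            assert scaled[pos] <= -0.8

    def test_locality_of_detection(self):
        # perturbing the curve far away from a valley and its scaling window
        # does not move that valley's detection
        v = np.ones(2000)
        v[500:520] = -0.2
        got1 = ltea(v, 50, threshold=-1.0, excl_width=30)
        v2 = v.copy()
        v2[1500:1520] = 0.5
        got2 = ltea(v2, 50, threshold=-1.0, excl_width=30)
        assert 500 <= got1.indices[0] <= 520
        assert got1.indices[0] in got2.indices

    def test_threshold_must_be_below_clip_value(self):
        with pytest.raises(ValueError):
            ltea(np.ones(10), 5, threshold=1.0)


class TestDefaultLocalWindow:
    def test_mean_gap_including_edges(self):
        from lsuss import ChangePointSet, default_local_window
        import numpy as np
        gt = ChangePointSet(np.array([100, 300]), n_ref=600)
        # segments 100, 200, 300 -> mean 200
        assert default_local_window(gt) == 200

    def test_empty_ground_truth_rejected(self):
        from lsuss import ChangePointSet, default_local_window
        import numpy as np
        import pytest
        with pytest.raises(ValueError):
            default_local_window(ChangePointSet(np.array([]), n_ref=10))
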