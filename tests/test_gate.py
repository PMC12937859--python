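import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfpgate import (
    DetectorConfig, FixedPointConfig, mav_strength, mad_strength,
    wa_strength, neo_strength, calibrate_threshold, gate,
    interception_at_fixed_miss, fixed_point_detect,
)


def brute_mav(x, Tw, step):
    return np.array([np.sum(np.abs(x[s:s + Tw]))
                     for s in range(0, len(x) - Tw + 1, step)])


class TestMav:
    def test_zero_input_gives_zero_strength(self):
        E = mav_strength(np.zeros(100), DetectorConfig(Tw=10))
        assert np.all(E.values == 0)

    def test_four_sample_window_sums_absolutes(self):
        E = mav_strength(np.array([1.0, -2.0, 3.0, -4.0]), DetectorConfig(Tw=4))
        assert E.values[-1] == 10.0

    def test_matches_naive_rolling_sum(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        cfg = DetectorConfig(Tw=32, step=7)
        np.testing.assert_allclose(mav_strength(x, cfg).values,
                                   brute_mav(x, 32, 7), rtol=1e-12)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            mav_strength(np.zeros(5), DetectorConfig(Tw=10))

    @given(a=st.floats(-50, 50, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, a):
        x = np.random.default_rng(1).normal(size=200)
        cfg = DetectorConfig(Tw=16)
        base = mav_strength(x, cfg).values
        np.testing.assert_allclose(mav_strength(a * x, cfg).values,
                                   np.abs(a) * base, rtol=1e-9, atol=1e-9)


class TestCompetitorFeatures:
    def test_constant_window_degenerate_values(self):
        x = np.full(64, 3.7)
        cfg = DetectorConfig(Tw=16)
        assert np.all(mad_strength(x, cfg).values == 0.0)
        np.testing.assert_allclose(wa_strength(x, cfg).values, 3.7)
        np.testing.assert_allclose(neo_strength(x, cfg).values, 0.0, atol=1e-12)

    def test_winsorized_average_clips_order_statistics(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        cfg = DetectorConfig(Tw=5)
        # 20/80% limits: [1,2,3,4,100] -> [2,2,3,4,4] -> mean 3.0
        out = wa_strength(x, cfg, limits=(0.2, 0.8))
        assert out.values[0] == pytest.approx(3.0)

    def test_mad_matches_brute_force(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        cfg = DetectorConfig(Tw=25, step=25)
        expected = [np.median(np.abs(w - np.median(w)))
                    for w in x[: 500 - 500 % 25].reshape(-1, 25)]
        np.testing.assert_allclose(mad_strength(x, cfg).values, expected)

    def test_neo_quadratic_in_amplitude(self):
        fs = 2000.0
        t = np.arange(2048) / fs
        cfg = DetectorConfig(Tw=64)
        base = neo_strength(np.sin(2 * np.pi * 40 * t), cfg).values.mean()
        quad = neo_strength(2 * np.sin(2 * np.pi * 40 * t), cfg).values.mean()
        assert quad == pytest.approx(4 * base, rel=1e-6)

    def test_neo_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            neo_strength(np.zeros(50), DetectorConfig(Tw=2))


class TestThresholdCalibration:
    def test_all_equal_values_give_that_value(self):
        assert calibrate_threshold(np.full(100, 5.0), 0.03) == 5.0

    def test_order_statistic_on_1_to_1000(self):
        v = np.random.default_rng(3).permutation(np.arange(1.0, 1001.0))
        vth = calibrate_threshold(v, 0.03)
        assert vth == 30.0
        assert np.sum(v > vth) == 970

    def test_monotone_in_quantile(self):
        v = np.random.default_rng(4).normal(size=500)
        qs = [0.01, 0.03, 0.1, 0.5, 0.9]
        vths = [calibrate_threshold(v, q) for q in qs]
        assert all(a <= b for a, b in zip(vths, vths[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([]), 0.03)


class TestGate:
    def test_flags_against_threshold(self):
        np.testing.assert_array_equal(gate(np.array([5.0, 12.0, 3.0]), 10.0),
                                      [False, True, False])

    def test_zero_threshold_opens_everything(self):
        E = np.abs(np.random.default_rng(5).normal(size=50))
        assert gate(E, 0.0).all()

    def test_tie_at_threshold_transmits(self):
        assert gate(np.array([10.0]), 10.0)[0]

    def test_raising_threshold_never_opens_more(self):
        E = np.random.default_rng(6).uniform(0, 100, 1000)
        opens = [gate(E, v).sum() for v in np.linspace(0, 100, 17)]
        assert all(a >= b for a, b in zip(opens, opens[1:]))

    def test_intercepted_fraction_matches_count(self):
        E = np.random.default_rng(7).uniform(0, 1, 500)
        vth = 0.4
        assert (~gate(E, vth)).mean() == np.count_nonzero(E < vth) / 500


class TestInterception:
    def test_exhaustive_count_example(self):
        rest = np.arange(1.0, 101.0)
        active = np.arange(50.0, 150.0)
        assert interception_at_fixed_miss(rest, active, 0.03) == pytest.approx(0.51)

    def test_disjoint_distributions_fully_intercepted(self):
        assert interception_at_fixed_miss(np.arange(10.0),
                                          np.arange(100.0, 200.0), 0.03) == 1.0

    def test_active_miss_within_requested_bound(self):
        rng = np.random.default_rng(8)
        active = rng.uniform(10, 20, 997)
        thr_equiv = calibrate_threshold(active, 0.05)
        assert np.mean(active < thr_equiv) <= 0.05


class TestFixedPoint:
    def test_small_accumulate_and_compare(self):
        codes = np.array([1, -2, 3], dtype=np.int64)
        flags = fixed_point_detect(codes, 5, DetectorConfig(Tw=3),
                                   FixedPointConfig(input_bits=6, acc_bits=8))
        assert flags[0]  # |1|+|2|+|3| = 6 >= 5

    def test_equivalence_with_float_gate_on_random_codes(self):
        rng = np.random.default_rng(9)
        codes = rng.integers(-32, 32, size=10_000)
        cfg = DetectorConfig(Tw=8, step=1)
        vth = 40
        fx = fixed_point_detect(codes, vth, cfg,
                                FixedPointConfig(input_bits=6, acc_bits=9))
        fl = gate(mav_strength(codes.astype(float), cfg), float(vth))
        np.testing.assert_array_equal(fx, fl)

    def test_accumulator_width_checked_at_construction(self):
        with pytest.raises(OverflowError, match="accumulator"):
            fixed_point_detect(np.zeros(64, dtype=np.int64), 1,
                               DetectorConfig(Tw=64),
                               FixedPointConfig(input_bits=12, acc_bits=12))

    def test_minimum_width_never_overflows_at_rails(self):
        # worst case: all samples at the negative rail of a 6-bit code
        Tw = 16
        codes = np.full(Tw, -32, dtype=np.int64)
        fx = FixedPointConfig(input_bits=6, acc_bits=6 + 4)
        flags = fixed_point_detect(codes, (1 << 10) - 1, DetectorConfig(Tw=Tw), fx)
        # |sum| = 16*32 = 512 < 2^10: accumulated without wraparound
        assert not flags[0]
        assert fixed_point_detect(codes, 512, DetectorConfig(Tw=Tw), fx)[0]

    def test_non_integer_codes_rejected(self):
        with pytest.raises(TypeError):
            fixed_point_detect(np.zeros(8), 1, DetectorConfig(Tw=4),
                               FixedPointConfig())
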