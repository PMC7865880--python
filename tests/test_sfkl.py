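"""Weight quantization, saturation-flooring requantizers, KL calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oinose import sfkl
from oinose.sfkl import (DegenerateScaleError, choose_exponent, kl_divergence,
                         max_search_exponent, quantize_weights,
                         requant_bitslice, saturate_floor)


class TestQuantizeWeights:
    def test_hand_worked_layer(self):
        res = quantize_weights({"l": np.array([1.0, -0.5, 0.25])})
        assert res.max_abs["l"] == 1.0 and res.scale["l"] == 127.0
        np.testing.assert_array_equal(res.q_weights["l"], [127, -64, 32])

    def test_all_zero_layer_raises(self):
        with pytest.raises(DegenerateScaleError):
            quantize_weights({"l": np.zeros(2)})

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30)
           .filter(lambda v: max(abs(x) for x in v) > 1e-6))
    @settings(deadline=None, derandomize=True)
    def test_max_weight_maps_to_full_scale_and_error_half_lsb(self, vals):
        res = quantize_weights({"l": np.array(vals)})
        q = res.q_weights["l"]
        assert np.abs(q).max() == 127
        err = np.abs(np.array(vals) - q / res.scale["l"])
        assert np.all(err <= 0.5 / res.scale["l"] + 1e-12)

    def test_half_away_from_zero_rounding(self):
        res = quantize_weights({"l": np.array([1.0, 0.5 / 127, -0.5 / 127])})
        np.testing.assert_array_equal(res.q_weights["l"], [127, 1, -1])

    def test_alternative_scale_conventions_clamp(self):
        res = quantize_weights({"l": np.array([1.0, -1.0])}, scale_convention=255)
        np.testing.assert_array_equal(res.q_weights["l"], [127, -128])


class TestSaturateFloor:
    @pytest.mark.parametrize("y,n,expected", [
        (1000, 3, 125),     # floor(125.0)
        (2000, 3, 127),     # 250 saturates high
        (-5, 1, -3),        # floor toward -inf
        (-300000, 10, -128),
        (126, 0, 126),
    ])
    def test_hand_worked_values(self, y, n, expected):
        assert saturate_floor(y, n) == expected

    def test_negative_exponent_rejected(self):
        with pytest.raises(ValueError):
            saturate_floor(1, -1)

    @given(st.integers(-2 ** 20, 2 ** 20), st.integers(-2 ** 20, 2 ** 20),
           st.integers(0, 12))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_y(self, a, b, n):
        lo, hi = min(a, b), max(a, b)
        assert saturate_floor(lo, n) <= saturate_floor(hi, n)


class TestRequantBitslice:
    @pytest.mark.parametrize("y,n,expected", [
        (-7, 0, 0),          # sign bit set -> fused ReLU
        (-7, 4, 0),
        (200, 1, 100),       # 200 >> 1, high bits clear
        (300, 1, 127),       # 150 overflows 7 bits -> saturate
        (127, 0, 127),
        (128, 0, 127),
    ])
    def test_hand_worked_values(self, y, n, expected):
        assert requant_bitslice(y, n, 20) == expected

    def test_width_and_exponent_contracts(self):
        with pytest.raises(OverflowError):
            requant_bitslice(1 << 19, 0, 20)
        with pytest.raises(ValueError):
            requant_bitslice(0, 13, 20)  # N + 7 > n_bits - 1

    def test_exhaustive_12bit_equivalence(self):
        """Bit slicing == clamp(floor(max(Y,0)/2^N), 0, 127), all 12-bit Y, all N."""
        ys = np.arange(-2048, 2048)
        for n in range(0, 5):  # admissible: N + 7 <= 11
            ref = np.clip(np.floor_divide(np.maximum(ys, 0), 2 ** n), 0, 127)
            np.testing.assert_array_equal(requant_bitslice(ys, n, 12), ref)

    @pytest.mark.parametrize("n_bits", [20, 22])
    def test_random_wide_equivalence(self, n_bits):
        rng = np.random.default_rng(n_bits)
        ys = rng.integers(-(1 << (n_bits - 1)), 1 << (n_bits - 1), size=20000)
        for n in (0, 3, 7, n_bits - 8):
            ref = np.clip(np.floor_divide(np.maximum(ys, 0), 2 ** n), 0, 127)
            np.testing.assert_array_equal(requant_bitslice(ys, n, n_bits), ref)


class TestKlDivergence:
    def test_exact_match_gives_zero(self):
        x = np.array([4.0, 8.0, 16.0])
        qy = np.array([1, 2, 4])
        assert kl_divergence(x, qy, 2) == 0.0

    def test_all_zero_float_side_gives_zero(self):
        assert kl_divergence(np.zeros(5), np.arange(5), 3) == 0.0

    def test_matches_naive_reimplementation(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 50, size=200)
        y = rng.integers(0, 1 << 15, size=200)
        n = 5
        qy = sfkl.saturate_floor(y, n)
        # independent naive evaluation of the summed log-ratio
        expected = 0.0
        for xi, qi in zip(x, qy):
            if xi > 1e-10:
                expected += xi * np.log(xi / max(qi * 2 ** n, 1e-10))
        assert kl_divergence(x, qy, n) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.zeros(3), np.zeros(4), 0)


class TestExponentSearch:
    def test_max_search_exponent(self):
        assert max_search_exponent(127) == 0
        assert max_search_exponent(128) == 1
        assert max_search_exponent(5000) == 6

    @pytest.mark.parametrize("n_star", range(7))
    def test_recovers_exact_power_of_two_scale(self, n_star):
        """Activations that are exact k*2^N multiples calibrate to N."""
        k = np.arange(1, 128, dtype=np.int64)
        wide = k * 2 ** n_star
        floats = wide.astype(float)
        best, table = choose_exponent([floats], [wide], n_bits=22)
        assert best == n_star
        assert table[n_star] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_output_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            best, _ = choose_exponent([np.zeros(4)], [np.zeros(4, dtype=np.int64)],
                                      n_bits=20)
        assert best == 0

    def test_kl_ties_break_to_smaller_exponent(self):
        # zero float activations make every candidate's KL exactly 0: a tie
        # across the whole searched range, which must resolve to N=0
        wide = np.array([300, 600, 1200], dtype=np.int64)
        best, table = choose_exponent([np.zeros(3)], [wide], n_bits=20)
        assert len(table) > 1
        assert all(v == 0.0 for v in table.values())
        assert best == 0


class TestCalibrate:
    def test_deterministic_given_sample_list(self, trained_nobias, small_preprocessed):
        normalized, quantized, _, _ = small_preprocessed
        from oinose import evaluate
        wq = evaluate._quantize_model(trained_nobias, with_bias=False)
        runs = [
            sfkl.calibrate(trained_nobias, wq, normalized[:10], quantized[:10])
            for _ in range(2)
        ]
        assert runs[0].exponents == runs[1].exponents
        assert runs[0].kl_tables == runs[1].kl_tables

    def test_covers_all_non_pooling_layers(self, quantized_nobias):
        _, cal = quantized_nobias
        assert set(cal.exponents) == {"dwc1", "pwc1", "dwc2", "pwc2", "fc"}
        for name, table in cal.kl_tables.items():
            assert cal.exponents[name] == min(table, key=lambda n: (table[n], n))

    def test_json_round_trip(self, quantized_nobias):
        _, cal = quantized_nobias
        back = sfkl.CalibrationResult.from_json(cal.to_json())
        assert back.exponents == cal.exponents
        assert back.n_samples == cal.n_samples

    def test_empty_calibration_set_rejected(self, trained_nobias):
        from oinose import evaluate
        wq = evaluate._quantize_model(trained_nobias, with_bias=False)
        with pytest.raises(ValueError):
            sfkl.calibrate(trained_nobias, wq, [], [])
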