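"""Integer pipeline stages: Winograd exactness, adder-tree/chunked identities,
accumulator-width enforcement, end-to-end int8 agreement with the float net."""

import numpy as np
import pytest

from oinose import evaluate, int_engine
from oinose.int_engine import (AccumulatorOverflowError, FixedPointConfig,
                               QuantizedTensor, direct_dwconv, fc_chunked,
                               forward_int8, maxpool_1x2, pointwise_conv,
                               winograd_f23_dwconv)


class TestWinograd:
    def test_identity_tap_kernel(self):
        x = np.arange(20)
        np.testing.assert_array_equal(winograd_f23_dwconv(x, [0, 1, 0]), x[1:-1])

    def test_hand_worked_tile(self):
        np.testing.assert_array_equal(
            winograd_f23_dwconv([1, 2, 3, 4], [1, 1, 1]), [6, 9])

    def test_exhaustive_int4_kernels(self):
        """Every int4 kernel, against direct convolution on a random int4 sequence."""
        rng = np.random.default_rng(0)
        x = rng.integers(-8, 8, size=64)
        for k0 in range(-8, 8):
            for k1 in range(-8, 8):
                for k2 in range(-8, 8):
                    k = [k0, k1, k2]
                    np.testing.assert_array_equal(
                        winograd_f23_dwconv(x, k), direct_dwconv(x, k))

    def test_exhaustive_int4_input_tiles(self):
        """All 16^4 int4 tiles at once: tiles laid out back to back align with
        the transform's stride-2 tiling, so in-tile outputs are comparable."""
        vals = np.arange(-8, 8)
        tiles = np.stack(np.meshgrid(vals, vals, vals, vals, indexing="ij"),
                         axis=-1).reshape(-1, 4)
        seq = tiles.ravel()
        for k in ([1, 1, 1], [3, -5, 2], [-8, 7, -8], [0, 0, 1]):
            out = winograd_f23_dwconv(seq, k)
            ref = direct_dwconv(seq, k)
            # positions 4i and 4i+1 use only tile i's four inputs
            pos = np.arange(len(tiles)) * 4
            np.testing.assert_array_equal(out[pos], ref[pos])
            np.testing.assert_array_equal(out[pos + 1], ref[pos + 1])

    def test_random_int8_cases_match_direct_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            n = int(rng.integers(4, 24))
            x = rng.integers(-128, 128, size=n)
            k = rng.integers(-128, 128, size=3)
            np.testing.assert_array_equal(winograd_f23_dwconv(x, k),
                                          direct_dwconv(x, k))

    def test_odd_output_length_handled(self):
        x = np.arange(5)  # 3 outputs: one full tile + direct tail
        np.testing.assert_array_equal(winograd_f23_dwconv(x, [1, 2, 3]),
                                      direct_dwconv(x, [1, 2, 3]))

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            winograd_f23_dwconv([1, 2, 3], [1, 1, 1])


class TestPointwise:
    def test_identity_weight_matrix(self):
        x = np.arange(12).reshape(3, 4)
        np.testing.assert_array_equal(pointwise_conv(x, np.eye(3, dtype=int)), x)

    def test_hand_worked_dot(self):
        x = np.array([[3], [-4]])
        w = np.array([[2, 5]])
        assert pointwise_conv(x, w)[0, 0] == -14

    def test_random_matches_naive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.integers(-128, 128, size=(6, 17))
            w = rng.integers(-128, 128, size=(4, 6))
            naive = np.array([[sum(int(w[o, c]) * int(x[c, t]) for c in range(6))
                               for t in range(17)] for o in range(4)])
            np.testing.assert_array_equal(pointwise_conv(x, w), naive)


class TestPoolAndFc:
    def test_pairwise_max(self):
        np.testing.assert_array_equal(maxpool_1x2(np.array([1, 5, 2, 2])), [5, 2])

    def test_odd_trailing_element_dropped(self):
        assert maxpool_1x2(np.array([7])).size == 0
        np.testing.assert_array_equal(maxpool_1x2(np.array([1, 5, 9])), [5])

    def test_random_pooling_matches_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.integers(-100, 100, size=(5, 58))
        ref = np.maximum(x[:, 0::2], x[:, 1::2])
        np.testing.assert_array_equal(maxpool_1x2(x), ref)

    def test_one_hot_row_selects_input(self):
        x = np.arange(290)
        w = np.zeros((7, 290), dtype=int)
        w[3, 42] = 1
        out = fc_chunked(x, w)
        assert out[3] == 42 and out.sum() == 42

    def test_chunked_equals_monolithic_dot(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 128, size=290)
        w = rng.integers(-128, 128, size=(7, 290))
        np.testing.assert_array_equal(fc_chunked(x, w), w @ x)

    def test_zero_input_zero_logits(self):
        np.testing.assert_array_equal(
            fc_chunked(np.zeros(10, dtype=int), np.ones((7, 10), dtype=int)),
            np.zeros(7))

    def test_non_chunkable_length_rejected(self):
        with pytest.raises(ValueError):
            fc_chunked(np.zeros(7, dtype=int), np.zeros((2, 7), dtype=int))


class TestFixedPoint:
    def test_width_invariants(self):
        with pytest.raises(ValueError):
            FixedPointConfig(dwc_acc_bits=8)
        with pytest.raises(ValueError):
            FixedPointConfig(overflow="wrap")

    def test_quantized_tensor_range_check(self):
        QuantizedTensor(np.array([-128, 127]), bits=8)
        with pytest.raises(ValueError):
            QuantizedTensor(np.array([128]), bits=8)
        with pytest.raises(ValueError):
            QuantizedTensor(np.array([-1]), bits=8, signed=False)

    def test_fc_accumulator_overflow_policies(self):
        x = np.full(290, 127, dtype=np.int64)
        w = np.full((7, 290), 127, dtype=np.int64)  # worst case: exceeds 22 bits
        with pytest.raises(AccumulatorOverflowError):
            fc_chunked(x, w, acc_bits=22, policy="error")
        sat = fc_chunked(x, w, acc_bits=22, policy="saturate")
        assert np.all(sat == (1 << 21) - 1)


class TestForwardInt8:
    def test_end_to_end_agreement_with_float(self, trained_nobias, quantized_nobias,
                                             small_preprocessed):
        """SF-KL int8 argmax agrees with the float model on >= 90% of samples."""
        normalized, quantized, x, y = small_preprocessed
        wq, cal = quantized_nobias
        float_pred = trained_nobias.predict(x)
        int_pred = np.array([
            forward_int8(q, wq, cal, spec=trained_nobias.spec)[0]
            for q in quantized
        ])
        assert np.mean(int_pred == float_pred) >= 0.90

    def test_bit_reproducible(self, trained_nobias, quantized_nobias,
                              small_preprocessed):
        _, quantized, _, _ = small_preprocessed
        wq, cal = quantized_nobias
        a = forward_int8(quantized[0], wq, cal, spec=trained_nobias.spec)
        b = forward_int8(quantized[0], wq, cal, spec=trained_nobias.spec)
        assert a[0] == b[0]
        np.testing.assert_array_equal(a[1], b[1])

    def test_no_overflow_on_default_pipeline(self, trained_nobias, quantized_nobias,
                                             small_preprocessed):
        """Default widths 20/22/22 hold the whole synthetic dataset (policy=error)."""
        _, quantized, _, _ = small_preprocessed
        wq, cal = quantized_nobias
        cfg = FixedPointConfig(overflow="error")
        for q in quantized:
            forward_int8(q, wq, cal, cfg, spec=trained_nobias.spec)

    def test_missing_scale_raises(self, trained_nobias, quantized_nobias,
                                  small_preprocessed):
        from oinose.sfkl import CalibrationResult
        _, quantized, _, _ = small_preprocessed
        wq, _ = quantized_nobias
        empty = CalibrationResult(exponents={}, kl_tables={}, n_samples=0)
        with pytest.raises(ValueError, match="no calibrated scale"):
            forward_int8(quantized[0], wq, empty, spec=trained_nobias.spec)

    def test_argmax_ties_break_to_lowest_index(self, trained_nobias,
                                               quantized_nobias):
        """Duplicate FC weight rows force tied logits; the lower class wins."""
        import copy
        wq, cal = quantized_nobias
        wq2 = copy.deepcopy(wq)
        wq2.q_weights["fc"][5] = wq2.q_weights["fc"][2]  # classes 2 and 5 tie
        x = np.zeros((10, 120), dtype=np.int64)
        x[:, :3] = 50
        pred, logits = forward_int8(x, wq2, cal, spec=trained_nobias.spec)
        assert logits[2] == logits[5]
        if logits.max() == logits[2]:
            assert pred == 2
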