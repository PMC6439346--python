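"""Grid layout, spectra, extrema detection, preprocessing, hypnograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroscene import (
    Hypnogram,
    SignalDataset,
    detect_extrema,
    grid_shape,
    histogram,
    hypnogram_stats,
    preprocess,
    psd,
    reshape_to_grid,
    tf_morlet,
)


def best_divisor_pair(n):
    """Enumerate divisor pairs (r, c), r >= c, minimizing r - c."""
    pairs = [(n // c, c) for c in range(1, n + 1) if n % c == 0 and n // c >= c]
    return min(pairs, key=lambda rc: rc[0] - rc[1])


class TestGridShape:
    def test_104_signals_give_13_by_8(self):
        assert grid_shape(104) == (13, 8)

    def test_single_signal(self):
        assert grid_shape(1) == (1, 1)

    def test_12_minimizes_divisor_gap(self):
        assert grid_shape(12) == best_divisor_pair(12) == (4, 3)

    def test_prime_falls_back_with_empty_cells(self):
        rows, cols = grid_shape(7)
        assert (rows, cols) == (4, 2)
        assert rows * cols - 7 == 1

    @pytest.mark.parametrize("n", list(range(1, 200)) + [1024, 4095])
    def test_layout_invariants(self, n):
        rows, cols = grid_shape(n)
        assert rows * cols >= n
        assert rows >= cols
        best = best_divisor_pair(n)
        if best[0] / best[1] <= 4 or n <= 3:
            assert (rows, cols) == best  # exact-divisor branch, no padding

    @given(st.integers(min_value=1, max_value=100_000))
    @settings(derandomize=True, max_examples=200)
    def test_layout_invariants_property(self, n):
        rows, cols = grid_shape(n)
        assert rows * cols >= n
        assert rows >= cols
        # Padding never exceeds a full row minus one cell.
        assert rows * cols - n < cols

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            grid_shape(0)


class TestReshapeToGrid:
    def test_row_major_flattening(self):
        ds = SignalDataset(data=np.zeros((2, 3, 50)), sf=100.0, time_axis=2)
        (rows, cols), mapping = reshape_to_grid(ds)
        assert (rows, cols) == grid_shape(6)
        assert [m["multi_index"] for m in mapping[:4]] == [
            (0, 0), (0, 1), (0, 2), (1, 0),
        ]

    def test_grid_filled_row_by_row(self):
        ds = SignalDataset(data=np.zeros((6, 40)), sf=10.0, time_axis=1)
        (rows, cols), mapping = reshape_to_grid(ds)
        cells = [(m["row"], m["col"]) for m in mapping]
        assert cells == [(f // cols, f % cols) for f in range(6)]

    def test_mapping_is_bijective(self):
        ds = SignalDataset(data=np.zeros((3, 5, 2, 30)), sf=10.0, time_axis=3)
        _, mapping = reshape_to_grid(ds)
        cells = {(m["row"], m["col"]) for m in mapping}
        flats = {m["flat"] for m in mapping}
        assert len(cells) == len(flats) == 30

    def test_single_signal_one_cell(self):
        ds = SignalDataset(data=np.zeros(100), sf=10.0, time_axis=0)
        (rows, cols), mapping = reshape_to_grid(ds)
        assert (rows, cols) == (1, 1)
        assert len(mapping) == 1


class TestPsd:
    def test_zero_signal_zero_power(self):
        freqs, power = psd(np.zeros(1024), sf=256.0)
        assert np.all(power == 0)

    def test_sine_peak_bin_contains_tone(self):
        sf, n = 256.0, 2048
        t = np.arange(n) / sf
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, power = psd(x, sf)
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(power)] - 10.0) <= df / 2 + 1e-9

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=16384)
        freqs, power = psd(x, sf=128.0)
        total = np.trapezoid(power, freqs)
        assert abs(total - x.var()) / x.var() < 0.10


class TestTfMorlet:
    def test_zero_signal_zero_map(self):
        power = tf_morlet(np.zeros(512), 128.0, [4.0, 8.0, 16.0])
        assert power.shape == (3, 512)
        assert np.all(power == 0)

    def test_pure_tone_ridge_within_one_bin(self):
        sf = 256.0
        t = np.arange(int(4 * sf)) / sf
        x = np.sin(2 * np.pi * 21.0 * t)
        freqs = np.arange(2.0, 40.0, 1.0)
        power = tf_morlet(x, sf, freqs)
        mid = power[:, power.shape[1] // 4 : -power.shape[1] // 4]
        ridge = freqs[np.argmax(mid.mean(axis=1))]
        assert abs(ridge - 21.0) <= 1.0

    def test_percent_norm_centers_stationary_noise(self):
        rng = np.random.default_rng(3)
        sf = 128.0
        x = rng.normal(size=int(8 * sf))
        power = tf_morlet(
            x, sf, [6.0, 12.0], norm="percent", baseline=(0.0, 8.0)
        )
        # Baseline == whole record: mean percent change is exactly zero.
        np.testing.assert_allclose(power.mean(axis=1), 0.0, atol=1e-9)

    def test_zscore_norm_standardizes_baseline(self):
        rng = np.random.default_rng(4)
        sf = 128.0
        x = rng.normal(size=int(8 * sf))
        power = tf_morlet(x, sf, [10.0], norm="zscore", baseline=(0.0, 8.0))
        assert power.mean() == pytest.approx(0.0, abs=1e-9)
        assert power.std() == pytest.approx(1.0, abs=1e-9)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError, match="freqs"):
            tf_morlet(np.zeros(256), 128.0, [70.0])

    def test_baseline_outside_record_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            tf_morlet(np.zeros(256), 128.0, [10.0], norm="percent", baseline=(0, 10))


class TestHistogram:
    def test_counts_sum_to_n(self, rng):
        x = rng.normal(size=500)
        counts, edges = histogram(x, nbins=13)
        assert counts.sum() == 500
        assert len(edges) == 14

    def test_uniform_ramp_equal_counts(self):
        counts, _ = histogram(np.arange(100, dtype=float), nbins=10)
        assert np.all(counts == 10)

    def test_matches_sort_based_oracle(self, rng):
        x = rng.uniform(0, 1, 200)
        counts, edges = histogram(x, nbins=8)
        xs = np.sort(x)
        want = [
            int(
                np.sum(
                    (xs >= edges[b]) & ((xs < edges[b + 1]) | ((b == 7) & (xs <= edges[8])))
                )
            )
            for b in range(8)
        ]
        np.testing.assert_array_equal(counts, want)


class TestDetectExtrema:
    def test_worked_example(self):
        idx, runs = detect_extrema(np.array([0.0, 5.0, 0.0, -5.0]), lower=-4, upper=4)
        np.testing.assert_array_equal(idx, [1, 3])
        assert runs == [(1, 2), (3, 4)]

    def test_thresholds_outside_range_empty(self):
        idx, runs = detect_extrema(np.sin(np.linspace(0, 10, 100)), -2.0, 2.0)
        assert len(idx) == 0 and runs == []

    def test_strictness_at_threshold(self):
        idx, _ = detect_extrema(np.array([4.0, 4.0001, -4.0, -4.0001]), -4.0, 4.0)
        np.testing.assert_array_equal(idx, [1, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_elementwise_oracle_and_runs_cover(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        lower, upper = -1.2, 1.0
        idx, runs = detect_extrema(x, lower, upper)
        want = [i for i, v in enumerate(x) if v > upper or v < lower]
        np.testing.assert_array_equal(idx, want)
        covered = sorted(i for s, e in runs for i in range(s, e))
        assert covered == want
        for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
            assert e1 < s2  # disjoint and maximal


class TestPreprocess:
    def test_demean(self, rng):
        x = rng.normal(loc=3.0, size=1000)
        assert abs(preprocess(x, 100.0, "demean").mean()) < 1e-12

    def test_detrend_removes_ramp(self):
        x = 2.0 + 0.5 * np.arange(200)
        np.testing.assert_allclose(preprocess(x, 100.0, "detrend"), 0.0, atol=1e-9)

    def test_smooth_preserves_constant_at_edges(self):
        out = preprocess(np.full(50, 2.0), 10.0, "smooth", window=7)
        np.testing.assert_allclose(out, 2.0, atol=1e-12)

    def test_smooth_is_truncated_moving_average(self, rng):
        x = rng.normal(size=30)
        out = preprocess(x, 10.0, "smooth", window=5)
        for i in range(30):
            lo, hi = max(0, i - 2), min(30, i + 3)
            assert out[i] == pytest.approx(x[lo:hi].mean(), abs=1e-12)

    def test_bandpass_attenuates_out_of_band_tone(self):
        sf = 256.0
        t = np.arange(int(8 * sf)) / sf
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)
        y = preprocess(x, sf, "filter", btype="bandpass", freq=(2.0, 10.0))
        freqs, p_in = psd(x, sf)
        _, p_out = psd(y, sf)
        bin40 = np.argmin(np.abs(freqs - 40.0))
        atten_db = 10 * np.log10(p_in[bin40] / p_out[bin40])
        assert atten_db >= 20.0

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="kind"):
            preprocess(np.zeros(10), 10.0, "sharpen")


class TestHypnogram:
    def test_all_wake_record(self):
        h = Hypnogram(stages=np.zeros(120, dtype=int), epoch_s=30.0)
        stats = hypnogram_stats(h)
        assert stats["Wake"]["minutes"] == pytest.approx(60.0)
        assert stats["Wake"]["percent"] == pytest.approx(100.0)

    def test_mixed_vector_against_counting_oracle(self, rng):
        stages = rng.choice([-1, 0, 1, 2, 3, 4], size=500)
        h = Hypnogram(stages=stages, epoch_s=20.0)
        stats = hypnogram_stats(h)
        from neuroscene.signal import STAGE_NAMES

        for code, name in STAGE_NAMES.items():
            count = int(np.sum(stages == code))
            assert stats[name]["epochs"] == count
            assert stats[name]["minutes"] == pytest.approx(count * 20.0 / 60.0)
        total = sum(s["percent"] for s in stats.values())
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            Hypnogram(stages=np.array([], dtype=int))

    def test_unknown_stage_code_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            Hypnogram(stages=np.array([0, 7]))
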