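"""Burst detection: Lee filter, IPT search, intensity search, summaries."""

import numpy as np
import pytest

import oracles
from conftest import trace_from_seconds
from digisense import IntensityBurstParams, IptBurstParams, bin_trace, \
    burst_intensity_summary, find_bursts_intensity, find_bursts_ipt, lee_filter
from digisense.synthdata import simulate_trace


class TestLeeFilter:
    def test_constant_series_unchanged(self):
        out = lee_filter([5, 5, 5, 5, 5], window_n=2, sigma0=3.0)
        np.testing.assert_array_equal(out, [5, 5, 5, 5, 5])

    def test_sigma0_zero_is_identity(self):
        x = [1.0, 7.0, 2.0, 9.0]
        np.testing.assert_array_equal(lee_filter(x, 1, 0.0), x)

    def test_spike_hand_evaluated(self):
        # direct evaluation of the formula for [0,0,10,0,0], n=1, sigma0=1:
        # center windows have mean 10/3, population variance 200/9,
        # gain 200/209 -> 30/209 at the flanks, 6090/627 at the spike
        out = lee_filter([0, 0, 10, 0, 0], window_n=1, sigma0=1.0)
        expected = [0.0, 30 / 209, 6090 / 627, 30 / 209, 0.0]
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_matches_naive_oracle_on_random_series(self, rng):
        x = rng.exponential(1.0, size=300)
        out = lee_filter(x, window_n=4, sigma0=0.7)
        np.testing.assert_allclose(out, oracles.lee_filter_naive(x, 4, 0.7), rtol=1e-10)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            lee_filter([1.0, 2.0], window_n=0, sigma0=1.0)


class TestIptSearch:
    def test_dense_run_is_single_burst(self):
        trace = trace_from_seconds(np.arange(10) * 10e-6, duration=1e-3)
        params = IptBurstParams(ipt_threshold=100e-6, min_photons=7)
        bs = find_bursts_ipt(trace, params)
        assert bs.count == 1
        assert bs.bursts[0].n_photons == 10

    def test_run_below_min_photons_discarded(self):
        trace = trace_from_seconds(np.arange(6) * 10e-6, duration=1e-3)
        params = IptBurstParams(ipt_threshold=100e-6, min_photons=7)
        assert find_bursts_ipt(trace, params).count == 0

    def test_empty_trace_gives_empty_set(self):
        trace = trace_from_seconds([], duration=1.0)
        params = IptBurstParams(ipt_threshold=100e-6, min_photons=7)
        assert find_bursts_ipt(trace, params).count == 0

    def test_matches_brute_force_on_seeded_trace(self):
        # 1 kHz background over 10 s with 50 bright injected transits
        trace, truth = simulate_trace(
            background_rate=1000.0, event_rate=5.0, brightness=40.0,
            transit_time=1e-3, duration=10.0, seed=99,
        )
        params = IptBurstParams(ipt_threshold=5e-6, min_photons=30)
        bs = find_bursts_ipt(trace, params)
        expected = oracles.ipt_bursts_naive(trace, params)
        assert bs.count == len(expected)
        times = trace.times_s
        for burst, (i, j, n) in zip(bs.bursts, expected):
            assert burst.n_photons == n
            assert burst.start_time == times[i]
            assert burst.end_time == times[j]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_burst_count_monotone_in_min_photons_and_threshold(self, seed):
        trace, _ = simulate_trace(
            background_rate=3000.0, event_rate=4.0, brightness=30.0,
            transit_time=5e-4, duration=3.0, seed=seed,
        )
        counts_m = [
            find_bursts_ipt(trace, IptBurstParams(ipt_threshold=50e-6, min_photons=m)).count
            for m in (5, 10, 20, 40)
        ]
        assert counts_m == sorted(counts_m, reverse=True)
        counts_t = [
            find_bursts_ipt(trace, IptBurstParams(ipt_threshold=t, min_photons=10)).count
            for t in (5e-6, 20e-6, 80e-6)
        ]
        assert counts_t == sorted(counts_t)

    def test_splitting_at_long_gap_preserves_bursts(self):
        rng = np.random.default_rng(3)
        first = np.sort(rng.uniform(0, 0.4, size=3000))
        second = 0.6 + np.sort(rng.uniform(0, 0.4, size=3000))
        params = IptBurstParams(ipt_threshold=100e-6, min_photons=7)
        whole = find_bursts_ipt(
            trace_from_seconds(np.concatenate([first, second]), duration=1.0), params
        )
        left = find_bursts_ipt(trace_from_seconds(first, duration=0.5), params)
        right = find_bursts_ipt(trace_from_seconds(second, duration=1.0), params)
        assert whole.count == left.count + right.count
        np.testing.assert_array_equal(
            np.sort(whole.n_photons),
            np.sort(np.concatenate([left.n_photons, right.n_photons])),
        )

    def test_well_separated_injected_bursts_all_recovered(self):
        # 50 photons over 50 µs: every filtered gap sits far below the
        # 5 µs threshold, so each transit is one and only one burst
        trace, truth = simulate_trace(
            background_rate=0.0, event_rate=2.0, brightness=50.0,
            transit_time=5e-5, duration=10.0, seed=11,
        )
        params = IptBurstParams(ipt_threshold=5e-6, min_photons=30)
        bs = find_bursts_ipt(trace, params)
        assert bs.count == len(truth)


class TestIntensitySearch:
    def test_degenerate_constant_bins_give_no_bursts(self):
        trace = trace_from_seconds(np.arange(100) * 1e-3 + 0.5e-3, duration=0.1)
        binned = bin_trace(trace, 1e-3)
        assert binned.counts.std() == 0
        bs = find_bursts_intensity(binned, IntensityBurstParams())
        assert bs.count == 0

    def test_spikes_match_direct_scan_oracle(self, rng):
        counts = rng.poisson(10.0, size=1000)
        spike_bins = [100, 300, 500, 700, 900]
        counts[spike_bins] = 200
        from digisense import BinnedTrace

        binned = BinnedTrace(counts=counts, bin_width=1e-3)
        params = IntensityBurstParams(sd_multiplier=5.0)
        bs = find_bursts_intensity(binned, params)
        expected = oracles.intensity_bursts_naive(list(counts), 5.0)
        assert bs.count == len(expected) == 5
        for burst, (i, j, total) in zip(bs.bursts, expected):
            assert burst.start_time == pytest.approx(i * 1e-3)
            assert burst.end_time == pytest.approx((j + 1) * 1e-3)
            assert burst.n_photons == total

    def test_default_threshold_is_five_sd(self):
        assert IntensityBurstParams().sd_multiplier == 5.0
        assert IntensityBurstParams().bin_width == 1e-3

    def test_single_bin_is_rejected(self):
        from digisense import BinnedTrace

        binned = BinnedTrace(counts=[5], bin_width=1e-3)
        with pytest.raises(ValueError):
            find_bursts_intensity(binned, IntensityBurstParams())


class TestSummary:
    def test_small_examples(self):
        from digisense.burstsearch import Burst, BurstSet

        bursts = BurstSet(
            bursts=[Burst(0.0, 0.1, n) for n in (1, 2, 3)], source_duration=1.0
        )
        s = burst_intensity_summary(bursts)
        assert s == {"count": 3, "mean": 2.0, "median": 2.0}
        single = BurstSet(bursts=[Burst(0.0, 0.1, 7)], source_duration=1.0)
        assert burst_intensity_summary(single)["median"] == 7.0

    def test_empty_set_marked_undefined(self):
        from digisense.burstsearch import BurstSet

        s = burst_intensity_summary(BurstSet(bursts=[], source_duration=1.0))
        assert s["count"] == 0
        assert np.isnan(s["mean"]) and np.isnan(s["median"])

    def test_median_matches_sort_oracle(self, rng):
        from digisense.burstsearch import Burst, BurstSet

        photons = rng.poisson(40, size=10_000) + 1
        bursts = BurstSet(
            bursts=[Burst(i * 1e-3, i * 1e-3, int(n)) for i, n in enumerate(photons)],
            source_duration=20.0,
        )
        srt = np.sort(photons)
        expected = 0.5 * (srt[4999] + srt[5000])
        assert burst_intensity_summary(bursts)["median"] == expected
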