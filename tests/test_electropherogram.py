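"""Electropherogram assembly, region integration and two-peak decomposition."""

import numpy as np
import pytest

import oracles
from digisense import Electropherogram, PhotonTrace, RegionSelection, assemble, \
    fit_two_gaussians, integrate_region
from digisense.burstsearch import Burst, BurstSet
from digisense.electropherogram import ScanEntry, ScanSeries, flip_positions
from digisense.errors import AlignmentError, RegionError


def make_scan(positions, counts, repeat_id=0, duration=5.0):
    """A scan repeat whose burst counts per position are given directly."""
    entries = []
    for x, n in zip(positions, counts):
        bursts = BurstSet(
            bursts=[Burst(i * 1e-3, i * 1e-3 + 1e-4, 10) for i in range(int(n))],
            source_duration=duration,
        )
        trace = PhotonTrace(timestamps=[], duration=duration, position=float(x))
        entries.append(ScanEntry(position=float(x), trace=trace, burst_set=bursts,
                                 mean_intensity=float(n) * 10 / duration))
    return ScanSeries(entries=tuple(entries), repeat_id=repeat_id)


POSITIONS = np.arange(500.0, 900.0, 50.0)


class TestAssemble:
    def test_single_repeat_mean_is_counts_sd_zero(self):
        counts = [1, 4, 9, 16, 9, 4, 1, 0]
        e = assemble([make_scan(POSITIONS, counts)])
        np.testing.assert_array_equal(e.counts_mean, counts)
        np.testing.assert_array_equal(e.counts_sd, 0.0)
        assert e.n_repeats == 1

    def test_identical_repeats_have_zero_sd(self):
        counts = [2, 5, 11, 5, 2, 1, 0, 0]
        scans = [make_scan(POSITIONS, counts, repeat_id=r) for r in range(3)]
        e = assemble(scans)
        np.testing.assert_array_equal(e.counts_sd, 0.0)
        np.testing.assert_array_equal(e.intensity_sd, 0.0)

    def test_mean_sd_match_two_pass_oracle(self, rng):
        all_counts = rng.poisson(20, size=(3, POSITIONS.size))
        scans = [make_scan(POSITIONS, c, repeat_id=r) for r, c in enumerate(all_counts)]
        e = assemble(scans)
        for j in range(POSITIONS.size):
            m, s = oracles.mean_sd_two_pass([float(c[j]) for c in all_counts])
            assert e.counts_mean[j] == pytest.approx(m)
            assert e.counts_sd[j] == pytest.approx(s)

    def test_mismatched_grids_raise_alignment_error(self):
        s1 = make_scan(POSITIONS, np.ones(POSITIONS.size))
        s2 = make_scan(POSITIONS + 5.0, np.ones(POSITIONS.size), repeat_id=1)
        with pytest.raises(AlignmentError):
            assemble([s1, s2])

    def test_flip_positions_mirrors_axis(self):
        scan = make_scan(POSITIONS, np.arange(POSITIONS.size))
        flipped = flip_positions(scan)
        np.testing.assert_allclose(
            flipped.positions, (POSITIONS.max() + POSITIONS.min()) - POSITIONS[::-1]
        )
        # counts follow their positions
        assert flipped.counts()[0] == scan.counts()[-1]


class TestIntegrateRegion:
    def test_single_position_across_repeats(self):
        pos = [700.0]
        scans = [make_scan(pos, [n], repeat_id=r) for r, n in enumerate([3, 4, 5])]
        res = integrate_region(assemble(scans), RegionSelection(650.0, 750.0))
        assert res["n_mean"] == pytest.approx(4.0)
        assert res["n_sd"] == pytest.approx(1.0)

    def test_whole_grid_gives_total(self, rng):
        counts = rng.poisson(10, size=POSITIONS.size)
        e = assemble([make_scan(POSITIONS, counts)])
        res = integrate_region(e, RegionSelection(0.0, 10_000.0))
        assert res["n_mean"] == counts.sum()

    def test_partition_additivity(self, rng):
        counts = rng.poisson(10, size=(3, POSITIONS.size))
        e = assemble([make_scan(POSITIONS, c, repeat_id=r) for r, c in enumerate(counts)])
        mid = 700.0
        left = integrate_region(e, RegionSelection(0.0, mid))
        right = integrate_region(e, RegionSelection(mid, 10_000.0))
        whole = integrate_region(e, RegionSelection(0.0, 10_000.0))
        assert left["n_mean"] + right["n_mean"] == pytest.approx(whole["n_mean"])

    def test_empty_overlap_raises(self):
        e = assemble([make_scan(POSITIONS, np.ones(POSITIONS.size))])
        with pytest.raises(RegionError):
            integrate_region(e, RegionSelection(5000.0, 6000.0))


def _gauss(x, area, center, sigma):
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _epherogram_from_profile(x, y):
    zeros = np.zeros_like(y)
    return Electropherogram(
        positions=x, counts_mean=y, counts_sd=zeros, intensity_mean=y,
        intensity_sd=zeros, n_repeats=1, counts_per_repeat=y[None, :],
        intensity_per_repeat=y[None, :],
    )


class TestTwoGaussianFit:
    X = np.arange(400.0, 1200.0, 31.7)

    def test_recovers_area_fractions_noiseless(self):
        y = _gauss(self.X, 0.84, 600.0, 80.0) + _gauss(self.X, 0.16, 950.0, 80.0)
        fit = fit_two_gaussians(_epherogram_from_profile(self.X, y))
        np.testing.assert_allclose(sorted(fit.fractions), [0.16, 0.84], atol=0.01)
        assert fit.converged

    def test_single_peak_degenerates_gracefully(self):
        y = _gauss(self.X, 1.0, 700.0, 80.0)
        fit = fit_two_gaussians(_epherogram_from_profile(self.X, y))
        assert min(fit.fractions) < 0.02

    def test_fractions_invariant_to_ordinate_rescaling(self):
        y = _gauss(self.X, 0.7, 600.0, 70.0) + _gauss(self.X, 0.3, 900.0, 90.0)
        f1 = fit_two_gaussians(_epherogram_from_profile(self.X, y))
        f2 = fit_two_gaussians(_epherogram_from_profile(self.X, 137.0 * y))
        np.testing.assert_allclose(f1.fractions, f2.fractions, rtol=1e-6)

    def test_monomer_bound_vs_free_probe_split(self):
        # bound and free probe peaks with the measured 586.5 : 110.0 area
        # ratio; fractions of the 700 nM total probe recover both pools
        y = _gauss(self.X, 110.0, 550.0, 80.0) + _gauss(self.X, 586.5, 900.0, 80.0)
        fit = fit_two_gaussians(_epherogram_from_profile(self.X, y))
        split = np.sort(fit.fractions) * 700.0
        assert split[0] == pytest.approx(110.0, rel=0.02)
        assert split[1] == pytest.approx(586.5, rel=0.02)

    def test_too_few_positions_rejected(self):
        x = self.X[:5]
        y = _gauss(x, 1.0, 500.0, 60.0)
        with pytest.raises(ValueError):
            fit_two_gaussians(_epherogram_from_profile(x, y))
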