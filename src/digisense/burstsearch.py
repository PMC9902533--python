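"""Single-molecule and single-particle burst detection.

Two detectors are provided, matching the two regimes met in practice:

* :func:`find_bursts_ipt` — the combined inter-photon-time (IPT) /
  photon-count threshold search used for single molecules.  The IPT
  sequence is first smoothed with a Lee filter so that isolated long gaps
  inside an otherwise dense photon run do not split a burst, then a burst
  is any maximal run of consecutive photons whose filtered gaps all stay
  at or below the IPT threshold, provided the run contains at least
  ``min_photons`` photons.  Canonical settings are 100 µs / 7 photons for
  small, moderately bright analytes and 5 µs / 30 photons for large,
  bright particles.

* :func:`find_bursts_intensity` — the binned intensity-threshold search
  used for very bright, rare particles (e.g. micron-scale condensates)
  riding on a bulk background.  Counts are binned (1 ms bins by default)
  and a burst is a maximal run of bins strictly exceeding
  ``mean + sd_multiplier * sd`` of the whole trace's bin-count
  distribution (5 SD by default).

Thresholds are converted to counter ticks by rounding toward zero so the
comparison stays exact on the timestamp grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phototrace import BinnedTrace, PhotonTrace, interphoton_ticks


@dataclass(frozen=True)
class IptBurstParams:
    """Parameters of the IPT / photon-count burst search.

    ``lee_sigma0`` is the noise scale of the Lee filter, in seconds of
    inter-photon time; if ``None`` it defaults to half the IPT threshold.
    """

    ipt_threshold: float
    min_photons: int
    lee_window_n: int = 4
    lee_sigma0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ipt_threshold <= 0:
            raise ValueError("ipt_threshold must be positive")
        if self.min_photons < 2:
            raise ValueError("min_photons must be >= 2")
        if self.lee_window_n < 1:
            raise ValueError("lee_window_n must be >= 1")
        if self.lee_sigma0 is not None and self.lee_sigma0 < 0:
            raise ValueError("lee_sigma0 must be non-negative")

    @property
    def sigma0(self) -> float:
        return self.ipt_threshold / 2 if self.lee_sigma0 is None else self.lee_sigma0


@dataclass(frozen=True)
class IntensityBurstParams:
    """Parameters of the binned intensity-threshold burst search."""

    bin_width: float = 1e-3
    sd_multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")


@dataclass(frozen=True)
class Burst:
    """One detected single-molecule / single-particle event."""

    start_time: float
    end_time: float
    n_photons: int
    peak_bin_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError("end_time precedes start_time")


@dataclass(frozen=True)
class BurstSet:
    """Time-ordered, non-overlapping bursts detected in one trace."""

    bursts: tuple
    source_duration: float
    params: object = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bursts", tuple(self.bursts))

    def __len__(self) -> int:
        return len(self.bursts)

    def __iter__(self):
        return iter(self.bursts)

    @property
    def count(self) -> int:
        return len(self.bursts)

    @property
    def n_photons(self) -> np.ndarray:
        return np.array([b.n_photons for b in self.bursts], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [b.start_time for b in self.bursts],
                "end_s": [b.end_time for b in self.bursts],
                "n_photons": [b.n_photons for b in self.bursts],
                "peak_bin_count": [b.peak_bin_count for b in self.bursts],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Lee filter
# ---------------------------------------------------------------------------

def lee_filter(series: Sequence[float], window_n: int, sigma0: float) -> np.ndarray:
    """Adaptive Lee filter over a centred window of ``2 * window_n + 1`` samples.

    Each sample is replaced by ``m + (x - m) * s2 / (s2 + sigma0**2)`` where
    ``m`` and ``s2`` are the running mean and (population) variance over the
    window, truncated at the edges.  Regions of constant signal (``s2 = 0``)
    collapse to the mean, while sharp features (``s2 >> sigma0**2``) pass
    through unchanged — which is exactly what a burst edge needs.
    ``sigma0 = 0`` is the identity filter.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if x.size == 0:
        return x.copy()
    if sigma0 == 0:
        return x.copy()
    n = x.size
    w = window_n
    shift = x[0]  # conditioning shift: keeps constant series exactly invariant
    xs = x - shift
    c1 = np.concatenate(([0.0], np.cumsum(xs)))
    c2 = np.concatenate(([0.0], np.cumsum(xs * xs)))
    i = np.arange(n)
    lo = np.maximum(0, i - w)
    hi = np.minimum(n, i + w + 1)
    cnt = hi - lo
    mean = (c1[hi] - c1[lo]) / cnt
    var = (c2[hi] - c2[lo]) / cnt - mean * mean
    var = np.maximum(var, 0.0)
    gain = var / (var + sigma0 * sigma0)
    return shift + mean + (xs - mean) * gain


# ---------------------------------------------------------------------------
# Burst searches
# ---------------------------------------------------------------------------

def _true_runs(mask: np.ndarray) -> np.ndarray:
    """Start/stop (half-open) indices of maximal runs of True in ``mask``."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges.reshape(-1, 2)


def find_bursts_ipt(trace: PhotonTrace, params: IptBurstParams) -> BurstSet:
    """Combined IPT / photon-count threshold burst search.

    A burst is a maximal run of consecutive photons in which every
    Lee-filtered inter-photon gap is ``<=`` the IPT threshold; a run of
    ``k`` qualifying gaps spans ``k + 1`` photons and is emitted when
    ``k + 1 >= min_photons``.  Burst boundaries are the first and last
    photon of the run.
    """
    if trace.n_photons < 2:
        return BurstSet(bursts=(), source_duration=trace.duration, params=params)
    ipts = interphoton_ticks(trace).astype(float)
    thr_ticks = int(params.ipt_threshold / trace.tick_resolution)
    sigma0_ticks = params.sigma0 / trace.tick_resolution
    filtered = lee_filter(ipts, params.lee_window_n, sigma0_ticks)
    qualifying = filtered <= thr_ticks
    times = trace.times_s
    bursts = []
    for g0, g1 in _true_runs(qualifying):
        n_phot = int(g1 - g0 + 1)  # k gaps span k+1 photons
        if n_phot >= params.min_photons:
            bursts.append(
                Burst(
                    start_time=float(times[g0]),
                    end_time=float(times[g1]),
                    n_photons=n_phot,
                )
            )
    return BurstSet(bursts=tuple(bursts), source_duration=trace.duration, params=params)


def find_bursts_intensity(binned: BinnedTrace, params: IntensityBurstParams) -> BurstSet:
    """Binned intensity-threshold burst search for bright, rare particles.

    The threshold ``T = mean + sd_multiplier * sd`` is taken from the
    distribution of all bin counts of the trace (population SD); a burst is
    a maximal run of consecutive bins with count strictly above ``T``.
    Burst boundaries are the start of the first and the end of the last
    bin of the run; ``n_photons`` is the summed count and
    ``peak_bin_count`` the maximum bin of the run.
    """
    counts = binned.counts
    if counts.size < 2:
        raise ValueError("at least two bins are required (SD undefined otherwise)")
    mean = counts.mean()
    sd = counts.std()  # population SD over all bins of this trace
    threshold = mean + params.sd_multiplier * sd
    above = counts > threshold
    bursts = []
    for b0, b1 in _true_runs(above):
        run = counts[b0:b1]
        bursts.append(
            Burst(
                start_time=binned.origin + b0 * binned.bin_width,
                end_time=binned.origin + b1 * binned.bin_width,
                n_photons=int(run.sum()),
                peak_bin_count=int(run.max()),
            )
        )
    duration = binned.n_bins * binned.bin_width
    return BurstSet(bursts=tuple(bursts), source_duration=duration, params=params)


def burst_intensity_summary(bursts: BurstSet) -> dict:
    """Mean / median photons-per-burst and burst count.

    The median is the preferred location statistic for burst brightness
    because burst-intensity distributions are heavy-tailed.  An empty set
    reports ``count = 0`` with NaN summaries.
    """
    n = bursts.n_photons
    if n.size == 0:
        return {"count": 0, "mean": float("nan"), "median": float("nan")}
    return {
        "count": int(n.size),
        "mean": float(n.mean()),
        "median": float(np.median(n)),
    }
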