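"""Spatial electropherograms from confocal step scans.

A free-flow electrophoresis experiment scans the confocal volume across
the separation chamber in steps; each step yields one photon trace, one
burst search, hence one digital molecule count.  This module assembles
those per-position results into an electropherogram (counts and mean
photon intensity versus channel position, averaged over scan repeats),
integrates elution regions, and decomposes two-species profiles into a
pair of Gaussian peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .burstsearch import BurstSet, IntensityBurstParams, IptBurstParams, \
    find_bursts_intensity, find_bursts_ipt
from .errors import AlignmentError, FitError, RegionError
from .phototrace import PhotonTrace, bin_trace


@dataclass(frozen=True)
class ScanEntry:
    """One scan step: position, its trace and (optionally) its burst set."""

    position: float
    trace: PhotonTrace
    burst_set: Optional[BurstSet] = None
    mean_intensity: Optional[float] = None  # photons / s

    def with_bursts(self, burst_set: BurstSet) -> "ScanEntry":
        return ScanEntry(self.position, self.trace, burst_set, self.mean_intensity)


@dataclass(frozen=True)
class ScanSeries:
    """One scan repeat: an ordered sequence of :class:`ScanEntry`."""

    entries: tuple
    repeat_id: int = 0

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        object.__setattr__(self, "entries", entries)
        pos = np.array([e.position for e in entries], dtype=float)
        if pos.size >= 2:
            d = np.diff(pos)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("positions must be strictly monotone within a scan")

    @property
    def positions(self) -> np.ndarray:
        return np.array([e.position for e in self.entries], dtype=float)

    def counts(self) -> np.ndarray:
        return np.array(
            [e.burst_set.count if e.burst_set is not None else np.nan
             for e in self.entries]
        )

    def intensities(self) -> np.ndarray:
        out = []
        for e in self.entries:
            if e.mean_intensity is not None:
                out.append(e.mean_intensity)
            else:
                out.append(e.trace.n_photons / e.trace.duration)
        return np.array(out, dtype=float)


def analyze_scan(scan: ScanSeries, params) -> ScanSeries:
    """Run the burst search on every trace of a scan repeat.

    ``params`` is an :class:`IptBurstParams` (IPT search) or an
    :class:`IntensityBurstParams` (binned intensity search).
    """
    entries = []
    for e in scan.entries:
        if isinstance(params, IptBurstParams):
            bs = find_bursts_ipt(e.trace, params)
        elif isinstance(params, IntensityBurstParams):
            bs = find_bursts_intensity(bin_trace(e.trace, params.bin_width), params)
        else:
            raise TypeError(f"unsupported burst parameter type {type(params)!r}")
        entries.append(e.with_bursts(bs))
    return ScanSeries(entries=tuple(entries), repeat_id=scan.repeat_id)


def flip_positions(scan: ScanSeries) -> ScanSeries:
    """Mirror the position axis (``x -> x_max + x_min - x``).

    The scan direction may differ between experiments while the direction
    of electrophoretic deflection does not; flipping re-expresses
    positions on a common axis.
    """
    pos = scan.positions
    ref = pos.max() + pos.min()
    entries = tuple(
        ScanEntry(ref - e.position, e.trace, e.burst_set, e.mean_intensity)
        for e in reversed(scan.entries)
    )
    return ScanSeries(entries=entries, repeat_id=scan.repeat_id)


@dataclass(frozen=True)
class Electropherogram:
    """Per-position molecule counts and intensities averaged over repeats.

    SDs use the sample (``n - 1``) denominator; a single repeat reports
    SD = 0.  The per-repeat matrices are retained so that region
    integration can be done per repeat before averaging.
    """

    positions: np.ndarray
    counts_mean: np.ndarray
    counts_sd: np.ndarray
    intensity_mean: np.ndarray
    intensity_sd: np.ndarray
    n_repeats: int
    counts_per_repeat: np.ndarray      # shape (n_repeats, n_positions)
    intensity_per_repeat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.positions,
                "counts_mean": self.counts_mean,
                "counts_sd": self.counts_sd,
                "intensity_mean_cps": self.intensity_mean,
                "intensity_sd_cps": self.intensity_sd,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class RegionSelection:
    """Half-open elution region ``[x_min, x_max)`` in micrometres."""

    x_min: float
    x_max: float

    def __post_init__(self) -> None:
        if self.x_max <= self.x_min:
            raise ValueError("x_max must exceed x_min")

    def mask(self, positions: np.ndarray) -> np.ndarray:
        return (positions >= self.x_min) & (positions < self.x_max)


def _sd(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Sample SD across repeats; one repeat gives 0 by convention."""
    if values.shape[axis] < 2:
        return np.zeros(values.shape[1 - axis] if values.ndim == 2 else ())
    return values.std(axis=axis, ddof=1)


def assemble(scans: Iterable[ScanSeries]) -> Electropherogram:
    """Average burst counts and intensities per position across repeats.

    All repeats must share the same position grid (flip first with
    :func:`flip_positions` if the scan direction alternated); mismatched
    grids raise :class:`AlignmentError` naming the offending positions.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("at least one scan repeat is required")
    ref = scans[0].positions
    for s in scans[1:]:
        pos = s.positions
        if pos.size != ref.size or not np.allclose(pos, ref):
            if pos.size == ref.size:
                bad = ref[~np.isclose(pos, ref)]
            else:
                bad = pos
            raise AlignmentError(
                f"repeat {s.repeat_id}: position grid mismatch at {np.round(bad, 3)}"
            )
    counts = np.vstack([s.counts() for s in scans])
    if np.isnan(counts).any():
        raise ValueError("scan entries lack burst sets; run analyze_scan first")
    intensity = np.vstack([s.intensities() for s in scans])
    return Electropherogram(
        positions=ref.copy(),
        counts_mean=counts.mean(axis=0),
        counts_sd=_sd(counts),
        intensity_mean=intensity.mean(axis=0),
        intensity_sd=_sd(intensity),
        n_repeats=len(scans),
        counts_per_repeat=counts,
        intensity_per_repeat=intensity,
    )


def integrate_region(e: Electropherogram, region: RegionSelection) -> dict:
    """Total molecule count in a region: per-repeat sum, then mean ± SD."""
    mask = region.mask(e.positions)
    if not mask.any():
        raise RegionError(
            f"region [{region.x_min}, {region.x_max}) overlaps no scan position"
        )
    per_repeat = e.counts_per_repeat[:, mask].sum(axis=1)
    return {
        "n_mean": float(per_repeat.mean()),
        "n_sd": float(_sd(per_repeat[:, None])[0]) if per_repeat.size > 1 else 0.0,
        "per_repeat": per_repeat,
    }


# ---------------------------------------------------------------------------
# Two-Gaussian peak decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianPeak:
    center: float   # µm
    width: float    # Gaussian sigma, µm
    area: float     # amplitude * width * sqrt(2*pi), ordinate units * µm


@dataclass(frozen=True)
class TwoGaussianFit:
    """Result of the two-Gaussian + constant-baseline decomposition."""

    peaks: tuple            # two GaussianPeak, ordered by center
    fractions: np.ndarray   # areas normalised to sum to 1
    baseline: float
    residual_norm: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.full_like(x, self.baseline)
        for p in self.peaks:
            amp = p.area / (p.width * np.sqrt(2 * np.pi))
            y = y + amp * np.exp(-0.5 * ((x - p.center) / p.width) ** 2)
        return y

    def to_dict(self) -> dict:
        return {
            "peaks": [
                {"center_um": p.center, "width_um": p.width, "area": p.area}
                for p in self.peaks
            ],
            "fractions": [float(f) for f in self.fractions],
            "baseline": self.baseline,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
        }


def _double_gaussian(x, a1, c1, s1, a2, c2, s2, b):
    return (
        b
        + a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
        + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2)
    )


def _initial_centers(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two highest interior local maxima; leftmost wins ties.

    Falls back to the global maximum plus the maximum outside its
    neighbourhood when fewer than two local maxima exist.
    """
    interior = np.flatnonzero(
        (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:])
    ) + 1
    if interior.size >= 2:
        # sort by height descending, then by position ascending (leftmost tie-break)
        order = sorted(interior, key=lambda i: (-y[i], x[i]))
        return float(x[order[0]]), float(x[order[1]])
    i0 = int(np.argmax(y))
    span = (x.max() - x.min()) / 4
    far = np.abs(x - x[i0]) > span
    if far.any():
        masked = np.where(far, y, -np.inf)
        i1 = int(np.argmax(masked))
    else:
        i1 = i0 + 1 if i0 + 1 < x.size else i0 - 1
    return float(x[i0]), float(x[i1])


def fit_two_gaussians(e: Electropherogram, channel: str = "counts") -> TwoGaussianFit:
    """Decompose an electropherogram into two Gaussian peaks + baseline.

    ``channel`` selects ``"counts"`` or ``"intensity"``.  Initialisation is
    deterministic and data-driven (the two highest local maxima, widths of
    three grid spacings); area fractions are invariant to rescaling the
    ordinate.  Non-convergence raises :class:`FitError` with diagnostics.
    """
    x = np.asarray(e.positions, dtype=float)
    if channel == "counts":
        y = np.asarray(e.counts_mean, dtype=float)
    elif channel == "intensity":
        y = np.asarray(e.intensity_mean, dtype=float)
    else:
        raise ValueError("channel must be 'counts' or 'intensity'")
    if x.size < 6:
        raise ValueError("at least 6 positions are required for a two-peak fit")

    spacing = float(np.median(np.abs(np.diff(x))))
    c1, c2 = _initial_centers(x, y)
    s0 = 3 * spacing
    b0 = max(float(y.min()), 0.0)
    a1 = max(float(np.interp(c1, x, y)) - b0, 1e-12)
    a2 = max(float(np.interp(c2, x, y)) - b0, 1e-12)
    p0 = [a1, c1, s0, a2, c2, s0, b0]
    span = x.max() - x.min()
    lower = [0, x.min() - span, spacing / 4, 0, x.min() - span, spacing / 4, 0]
    upper = [np.inf, x.max() + span, 2 * span, np.inf, x.max() + span, 2 * span, np.inf]
    try:
        popt, _ = curve_fit(
            _double_gaussian, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"two-Gaussian fit did not converge: {exc}") from exc
    a1, c1, s1, a2, c2, s2, b = popt
    peaks = [
        GaussianPeak(center=float(c), width=float(s), area=float(a * s * np.sqrt(2 * np.pi)))
        for a, c, s in ((a1, c1, s1), (a2, c2, s2))
    ]
    peaks.sort(key=lambda p: p.center)
    areas = np.array([p.area for p in peaks])
    total = areas.sum()
    if total <= 0:
        raise FitError("two-Gaussian fit degenerated to zero total area")
    resid = y - _double_gaussian(x, *popt)
    return TwoGaussianFit(
        peaks=tuple(peaks),
        fractions=areas / total,
        baseline=float(b),
        residual_norm=float(np.linalg.norm(resid)),
        converged=True,
    )
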