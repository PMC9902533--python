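"""Photon arrival-time traces and their binned representations.

The atomic measurement of a confocal single-molecule scan is a sequence of
photon arrival times recorded by a time-correlated single-photon counting
unit.  Arrival times are stored as integer ticks on the counter grid
(16 ps per tick for the hardware emulated here) so that all downstream
arithmetic — inter-photon times, binning, threshold comparisons — stays
bit-exact.  A trace additionally carries the scan metadata needed to turn
counts into concentrations: trace duration, channel position and laser
power.

Two on-disk formats are supported:

* a plain-text CSV dialect with one integer tick per line and
  ``#``-prefixed header lines (``tick_ps``, ``duration_s``, optionally
  ``position_um``, ``laser_power_uW``, ``repeat_id``);
* read-only photon-HDF5 (``/photon_data/timestamps`` plus
  ``/photon_data/timestamps_specs/timestamps_unit``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DataError

#: seconds per counter tick of the emulated TCSPC hardware
DEFAULT_TICK_S = 16e-12


@dataclass(frozen=True)
class PhotonTrace:
    """An ordered photon arrival-time trace.

    Parameters
    ----------
    timestamps : array of int
        Photon arrival times in integer counter ticks, non-decreasing and
        within ``[0, duration / tick_resolution]``.
    duration : float
        Trace length in seconds (always explicit, never inferred from the
        last photon).
    tick_resolution : float, optional
        Seconds per tick; 16 ps by default.
    position : float, optional
        Channel coordinate of the scan step, in micrometres.
    laser_power : float, optional
        Excitation power in microwatts (metadata only).
    repeat_id : int, optional
        Index of the scan repeat this trace belongs to.
    """

    timestamps: np.ndarray
    duration: float
    tick_resolution: float = DEFAULT_TICK_S
    position: Optional[float] = None
    laser_power: Optional[float] = None
    repeat_id: Optional[int] = None

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        object.__setattr__(self, "timestamps", ts)
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.tick_resolution <= 0:
            raise ValueError("tick_resolution must be positive")
        if ts.ndim != 1:
            raise DataError("timestamps must be one-dimensional")
        if ts.size:
            diffs = np.diff(ts)
            bad = np.flatnonzero(diffs < 0)
            if bad.size:
                i = int(bad[0])
                raise DataError(
                    f"timestamps not non-decreasing: index {i + 1} "
                    f"({ts[i + 1]}) precedes index {i} ({ts[i]})"
                )
            max_tick = self.duration / self.tick_resolution
            if ts[0] < 0 or ts[-1] > max_tick:
                raise DataError(
                    "timestamps outside [0, duration/tick_resolution] "
                    f"(last tick {ts[-1]}, limit {max_tick:.0f})"
                )

    @property
    def n_photons(self) -> int:
        return int(self.timestamps.size)

    @property
    def times_s(self) -> np.ndarray:
        """Arrival times in seconds (float64)."""
        return self.timestamps * self.tick_resolution


@dataclass(frozen=True)
class BinnedTrace:
    """Per-bin photon counts over half-open intervals ``[k*w, (k+1)*w)``."""

    counts: np.ndarray
    bin_width: float
    origin: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.origin + np.arange(self.n_bins) * self.bin_width

    @property
    def total(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {
    "tick_ps": float,
    "duration_s": float,
    "position_um": float,
    "laser_power_uW": float,
    "repeat_id": int,
}


def read_timestamps(path, format: str = "csv-ticks") -> PhotonTrace:
    """Read a photon trace from disk.

    ``format`` is ``"csv-ticks"`` (the package's plain-text dialect) or
    ``"photon-hdf5"``.  Unsorted timestamps raise :class:`DataError` rather
    than being silently sorted; a missing tick resolution raises
    :class:`ConfigurationError`.
    """
    path = Path(path)
    if format == "csv-ticks":
        return _read_csv(path)
    if format == "photon-hdf5":
        return _read_photon_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> PhotonTrace:
    header: dict = {}
    ticks: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key = key.strip()
                    if key in _HEADER_KEYS:
                        header[key] = _HEADER_KEYS[key](value.strip())
                continue
            ticks.append(int(line))
    if "tick_ps" not in header:
        raise ConfigurationError(f"{path}: header line '# tick_ps: <ps>' is required")
    if "duration_s" not in header:
        raise ConfigurationError(f"{path}: header line '# duration_s: <s>' is required")
    return PhotonTrace(
        timestamps=np.asarray(ticks, dtype=np.int64),
        duration=header["duration_s"],
        tick_resolution=header["tick_ps"] * 1e-12,
        position=header.get("position_um"),
        laser_power=header.get("laser_power_uW"),
        repeat_id=header.get("repeat_id"),
    )


def _read_photon_hdf5(path: Path) -> PhotonTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        try:
            ts = fh["/photon_data/timestamps"][:]
        except KeyError as exc:
            raise DataError(f"{path}: no /photon_data/timestamps dataset") from exc
        try:
            unit = float(fh["/photon_data/timestamps_specs/timestamps_unit"][()])
        except KeyError as exc:
            raise ConfigurationError(
                f"{path}: missing timestamps_specs/timestamps_unit"
            ) from exc
        if "acquisition_duration" in fh:
            duration = float(fh["/acquisition_duration"][()])
        else:
            raise ConfigurationError(
                f"{path}: missing /acquisition_duration (duration is never inferred)"
            )
    return PhotonTrace(timestamps=ts, duration=duration, tick_resolution=unit)


def write_timestamps(trace: PhotonTrace, path) -> None:
    """Write ``trace`` in the CSV-ticks dialect (lossless round trip)."""
    path = Path(path)
    lines = [f"# tick_ps: {trace.tick_resolution * 1e12:.10g}",
             f"# duration_s: {trace.duration!r}"]
    if trace.position is not None:
        lines.append(f"# position_um: {trace.position!r}")
    if trace.laser_power is not None:
        lines.append(f"# laser_power_uW: {trace.laser_power!r}")
    if trace.repeat_id is not None:
        lines.append(f"# repeat_id: {trace.repeat_id}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, trace.timestamps, fmt="%d")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bin_trace(trace: PhotonTrace, bin_width: float = 1e-3) -> BinnedTrace:
    """Bin photon counts into half-open intervals of ``bin_width`` seconds.

    The number of bins is ``ceil(duration / bin_width)`` and the total count
    is conserved; a photon landing exactly on ``duration`` (the closed upper
    edge of the trace) is assigned to the last bin.  The bin width is
    converted to ticks by rounding toward zero, so widths commensurate with
    the tick grid bin exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    bin_ticks = int(bin_width / trace.tick_resolution)
    if bin_ticks < 1:
        raise ValueError("bin_width is below one counter tick")
    n_bins = math.ceil(trace.duration / bin_width)
    idx = trace.timestamps // bin_ticks
    idx = np.minimum(idx, n_bins - 1)  # photon exactly at trace end
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrace(counts=counts, bin_width=bin_width, origin=0.0)


def interphoton_times(trace: PhotonTrace) -> np.ndarray:
    """Inter-photon times (seconds).  Fewer than two photons gives an empty array."""
    if trace.n_photons < 2:
        return np.empty(0, dtype=float)
    return np.diff(trace.timestamps) * trace.tick_resolution


def interphoton_ticks(trace: PhotonTrace) -> np.ndarray:
    """Inter-photon times in integer ticks (used by the burst search)."""
    if trace.n_photons < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(trace.timestamps)
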