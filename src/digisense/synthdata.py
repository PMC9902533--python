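"""Seeded generators for photon traces and full step-scan experiments.

Every stage of the analysis pipeline is testable without instrument data
through three generators:

* :func:`simulate_trace` — one confocal trace: homogeneous Poisson
  background photons plus transit events arriving as a Poisson process,
  each emitting a Poisson-distributed number of photons spread uniformly
  over its transit window.  Ground truth (event start times and photon
  counts) is returned alongside the trace.

* :func:`simulate_scan` — a full free-flow electrophoresis step scan:
  each species elutes at a mobility-dependent channel position with a
  Gaussian spatial spread, and the per-position event rate is set by
  inverting the flux relation used in quantification, so running the
  complete analysis pipeline on the output recovers the input
  concentrations to within Poisson counting error.

* :func:`simulate_fcs_trace` — Brownian motion of point emitters through
  a 3D Gaussian detection profile, for exercising the correlation
  analysis with a known diffusion time and occupancy.

All generators are bit-reproducible for a given seed: child random
streams are spawned deterministically per repeat and position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .electropherogram import ScanEntry, ScanSeries
from .phototrace import DEFAULT_TICK_S, PhotonTrace
from .quantify import N_A, ExperimentGeometry

_UL_PER_H_TO_L_PER_S = 1e-6 / 3600.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One fluorescent species in a simulated separation.

    ``mobility`` (m² V⁻¹ s⁻¹) is used with the field and residence time to
    place the elution center unless ``elution_center`` (µm) is given
    directly.  ``brightness`` is the mean photons emitted per confocal
    transit and ``transit_time`` the transit duration in seconds.
    """

    name: str
    concentration: float            # molar
    brightness: float               # mean photons per transit
    transit_time: float             # s
    elution_sigma: float            # µm
    mobility: Optional[float] = None
    elution_center: Optional[float] = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.brightness <= 0 or self.transit_time <= 0:
            raise ValueError("brightness and transit_time must be positive")
        if self.elution_sigma <= 0:
            raise ValueError("elution_sigma must be positive")

    def center(self, injection_position: float, field_v_per_m: Optional[float],
               residence_time: Optional[float]) -> float:
        if self.elution_center is not None:
            return self.elution_center
        if self.mobility is None or field_v_per_m is None or residence_time is None:
            raise ValueError(
                f"species {self.name!r}: either elution_center or "
                "(mobility, field, residence_time) must be provided"
            )
        deflection_m = self.mobility * field_v_per_m * residence_time
        return injection_position + deflection_m * 1e6  # m -> µm


@dataclass(frozen=True)
class SceneConfig:
    """A complete simulated step-scan experiment."""

    species: tuple
    background_rate: float          # photons / s
    geometry: ExperimentGeometry
    positions: np.ndarray           # µm grid
    seed: int
    field: Optional[float] = None           # V/m (effective, after voltage efficiency)
    residence_time: Optional[float] = None  # s in the deflection zone
    n_repeats: int = 3
    injection_position: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class SimulatedScan:
    """Simulation output: scan repeats plus the ground-truth event table."""

    scans: tuple                    # tuple of ScanSeries
    events: pd.DataFrame            # repeat, position_um, species, t_start_s, n_photons


# ---------------------------------------------------------------------------
# Single-trace generator
# ---------------------------------------------------------------------------

def _sample_photons(rng: np.random.Generator, duration: float, background_rate: float,
                    event_specs: Sequence[tuple]) -> tuple[np.ndarray, list]:
    """Photon times (s, unsorted) and ground-truth records.

    ``event_specs`` is a sequence of ``(rate, brightness, transit, label)``.
    Event start times are uniform on ``[0, duration - transit]`` so transits
    are never truncated by the trace edges.
    """
    chunks = []
    truth: list[dict] = []
    n_bg = rng.poisson(background_rate * duration)
    if n_bg:
        chunks.append(rng.uniform(0.0, duration, size=n_bg))
    for rate, brightness, transit, label in event_specs:
        if rate <= 0:
            continue
        n_events = rng.poisson(rate * duration)
        window = max(duration - transit, 0.0)
        for _ in range(n_events):
            start = rng.uniform(0.0, window)
            n_phot = rng.poisson(brightness)
            if n_phot:
                chunks.append(start + rng.uniform(0.0, transit, size=n_phot))
            truth.append({"species": label, "t_start_s": start, "n_photons": int(n_phot)})
    if chunks:
        times = np.concatenate(chunks)
    else:
        times = np.empty(0, dtype=float)
    return times, truth


def _to_trace(times_s: np.ndarray, duration: float, tick: float, **meta) -> PhotonTrace:
    ticks = np.floor(times_s / tick).astype(np.int64)
    ticks.sort()
    return PhotonTrace(timestamps=ticks, duration=duration, tick_resolution=tick, **meta)


def simulate_trace(background_rate: float, event_rate: float, brightness: float,
                   transit_time: float, duration: float, seed: int,
                   tick_resolution: float = DEFAULT_TICK_S,
                   position: Optional[float] = None) -> tuple[PhotonTrace, pd.DataFrame]:
    """Simulate one photon trace with known transit events.

    Returns the trace and a ground-truth table (event start times and
    photon counts) sorted by start time.  Identical seeds give bit-identical
    timestamp sequences.
    """
    if background_rate < 0 or event_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    specs = [(event_rate, brightness, transit_time, "event")] if event_rate > 0 else []
    times, truth = _sample_photons(rng, duration, background_rate, specs)
    trace = _to_trace(times, duration, tick_resolution, position=position)
    events = pd.DataFrame(truth, columns=["species", "t_start_s", "n_photons"])
    if len(events):
        events = events.sort_values("t_start_s", ignore_index=True)
    return trace, events


# ---------------------------------------------------------------------------
# Step-scan generator
# ---------------------------------------------------------------------------

def _position_rates(scene: SceneConfig, species: SpeciesSpec) -> np.ndarray:
    """Expected transit events per second at each scan position.

    Inverts the flux relation: of the total molecular flux
    ``F = c * N_A * Q``, the confocal volume at position ``x`` intercepts
    the fraction ``p(x) * (pi/4) * z * w / h`` where ``p`` is the spatial
    elution profile (a Gaussian density in µm⁻¹).
    """
    g = scene.geometry
    F = species.concentration * N_A * g.Q_sample * _UL_PER_H_TO_L_PER_S
    center = species.center(scene.injection_position, scene.field, scene.residence_time)
    x = scene.positions
    p = np.exp(-0.5 * ((x - center) / species.elution_sigma) ** 2) / (
        species.elution_sigma * math.sqrt(2 * math.pi)
    )
    covered = (
        _norm_cdf((x.max() + g.d_step / 2 - center) / species.elution_sigma)
        - _norm_cdf((x.min() - g.d_step / 2 - center) / species.elution_sigma)
    )
    if covered < 0.99:
        warnings.warn(
            f"species {species.name!r} elutes partly outside the position grid "
            f"({100 * (1 - covered):.1f}% of its mass truncated)",
            stacklevel=3,
        )
    detect_fraction = (math.pi / 4) * g.z * g.w / g.h  # µm² / µm -> µm; times p (µm⁻¹)
    return F * p * detect_fraction


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def simulate_scan(scene: SceneConfig, tick_resolution: float = DEFAULT_TICK_S) -> SimulatedScan:
    """Simulate a full step-scan experiment with ``scene.n_repeats`` repeats.

    Burst sets are left unset on the returned :class:`ScanSeries`; run
    :func:`digisense.electropherogram.analyze_scan` to fill them, then the
    usual assemble / integrate / quantify chain applies.
    """
    rates = {sp.name: _position_rates(scene, sp) for sp in scene.species}
    duration = scene.geometry.t
    root = np.random.SeedSequence(scene.seed)
    repeat_seqs = root.spawn(scene.n_repeats)
    scans = []
    all_events = []
    for r, rseq in enumerate(repeat_seqs):
        pos_seqs = rseq.spawn(scene.positions.size)
        entries = []
        for i, (x, pseq) in enumerate(zip(scene.positions, pos_seqs)):
            rng = np.random.default_rng(pseq)
            specs = [
                (rates[sp.name][i], sp.brightness, sp.transit_time, sp.name)
                for sp in scene.species
            ]
            times, truth = _sample_photons(rng, duration, scene.background_rate, specs)
            trace = _to_trace(times, duration, tick_resolution,
                              position=float(x), repeat_id=r)
            entries.append(ScanEntry(position=float(x), trace=trace))
            for rec in truth:
                rec.update(repeat=r, position_um=float(x))
                all_events.append(rec)
        scans.append(ScanSeries(entries=tuple(entries), repeat_id=r))
    events = pd.DataFrame(
        all_events, columns=["repeat", "position_um", "species", "t_start_s", "n_photons"]
    )
    return SimulatedScan(scans=tuple(scans), events=events)


# ---------------------------------------------------------------------------
# Brownian-dynamics FCS trace
# ---------------------------------------------------------------------------

def simulate_fcs_trace(N: float, tau_D: float, kappa: float, brightness_cps: float,
                       duration: float, dt: float, seed: int,
                       box_factor: float = 8.0,
                       tick_resolution: float = DEFAULT_TICK_S) -> PhotonTrace:
    """Photon trace of point emitters diffusing through a Gaussian focus.

    ``N`` is the mean occupancy of the effective volume, ``tau_D`` the
    lateral diffusion time and ``kappa`` the axial ratio.  Molecules move
    by Brownian steps in a periodic box of ``box_factor`` lateral radii
    per side; the detected intensity is a sum of 3D Gaussian profile
    weights and photons are drawn per step from a Poisson law.  Lengths
    are expressed in units of the lateral radius, so only ``tau_D`` and
    ``kappa`` carry physical meaning.
    """
    if min(N, tau_D, kappa, brightness_cps, duration, dt) <= 0:
        raise ValueError("all parameters must be positive")
    rng = np.random.default_rng(seed)
    # box: [-B/2, B/2] laterally, [-B*kappa/2, B*kappa/2] axially (units of w0)
    B = box_factor
    v_eff = math.pi**1.5 * kappa          # in units of w0^3
    v_box = B * B * B * kappa
    n_mol = max(int(round(N * v_box / v_eff)), 1)
    n_steps = int(math.ceil(duration / dt))
    sigma_step = math.sqrt(2.0 * dt / (4.0 * tau_D))  # sqrt(2 D dt), D = w0^2/(4 tau_D) = 1/(4 tau_D)

    pos = rng.uniform(-0.5, 0.5, size=(n_mol, 3)) * np.array([B, B, B * kappa])
    half = np.array([B / 2, B / 2, B * kappa / 2])
    chunks = []
    t0 = 0.0
    for _ in range(n_steps):
        pos += rng.normal(0.0, sigma_step, size=pos.shape)
        pos = (pos + half) % (2 * half) - half  # periodic wrap
        weight = np.exp(
            -2.0 * (pos[:, 0] ** 2 + pos[:, 1] ** 2) - 2.0 * (pos[:, 2] / kappa) ** 2
        ).sum()
        n_phot = rng.poisson(brightness_cps * weight * dt)
        if n_phot:
            chunks.append(t0 + rng.uniform(0.0, dt, size=n_phot))
        t0 += dt
    times = np.concatenate(chunks) if chunks else np.empty(0)
    times = times[times < duration]
    return _to_trace(times, duration, tick_resolution)
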