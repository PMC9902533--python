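"""From digital molecule counts to absolute concentrations and binding arithmetic.

The digital readout of a step scan is a molecule count per trace.  Because
the confocal volume samples only a sliver of the chamber cross-section,
the count converts to the total molecular flux through the device as

    F_total = (n / t) * (h * d_step) / ((pi/4) * z * w)

where ``t`` is the trace duration, ``h`` the chamber height, ``d_step``
the scan step, and ``z`` and ``w`` the axial and lateral extent of the
confocal detection cross-section.  Dividing the flux by the volumetric
sample flow rate gives the absolute number concentration,

    c = F_total / (N_A * Q_sample).

Downstream of the concentration estimate live the binding-arithmetic
helpers used to interpret an assay: back-calculating the target
concentration from a 1:1 equilibrium, binding-site concentrations,
valency from burst-intensity ratios, and the condensate block (volume
fraction, dense-phase concentration, mass density, partition fractions).

Uncertainties are propagated to first order from the repeat-count SD
only; device geometry is treated as exact, matching how repeat scatter
is reported in practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy.constants import N_A  # 6.02214076e23, exact SI

from .errors import ConfigurationError, InfeasibleBindingError

__all__ = [
    "N_A",
    "ExperimentGeometry",
    "BindingModel",
    "NetCount",
    "QuantResult",
    "CondensateMetrics",
    "net_count",
    "total_flux",
    "number_concentration",
    "quantify_counts",
    "target_from_equilibrium",
    "binding_site_concentration",
    "sites_per_particle",
    "valency_from_intensities",
    "condensate_volume_fraction",
    "dense_phase_concentration",
    "partition_fractions",
    "concentration_from_scans",
]

_UL_PER_H_TO_L_PER_S = 1e-6 / 3600.0


@dataclass(frozen=True)
class ExperimentGeometry:
    """Device and acquisition geometry needed by the flux conversion.

    All lengths in micrometres, flow rate in µL/h, trace duration in
    seconds.  Typical values for the emulated device: ``h = 28``,
    ``d_step = 31.7``, ``z = 3``, ``w = 0.4``, ``Q_sample = 70``,
    ``t = 5``.
    """

    h: float
    d_step: float
    z: float
    w: float
    Q_sample: float
    t: float

    def __post_init__(self) -> None:
        for name in ("h", "d_step", "z", "w", "Q_sample", "t"):
            v = getattr(self, name)
            if v is None or not (v > 0):
                raise ConfigurationError(f"geometry field {name!r} must be positive, got {v!r}")

    @property
    def cross_section_factor(self) -> float:
        """(h * d_step) / ((pi/4) * z * w), dimensionless."""
        return (self.h * self.d_step) / (math.pi / 4 * self.z * self.w)


@dataclass(frozen=True)
class BindingModel:
    """1:1 probe–analyte reaction P + A <-> PA.

    ``k_on`` has no default: published on-rates vary over orders of
    magnitude and a silent default would hide that choice.  ``k_off`` is
    derived as ``K_d * k_on`` unless given, in which case consistency is
    enforced to 1e-12 relative.
    """

    K_d: float
    k_on: float
    k_off: Optional[float] = None

    def __post_init__(self) -> None:
        if self.K_d <= 0 or self.k_on <= 0:
            raise ValueError("K_d and k_on must be positive")
        if self.k_off is None:
            object.__setattr__(self, "k_off", self.K_d * self.k_on)
        else:
            if abs(self.K_d - self.k_off / self.k_on) > 1e-12 * self.K_d:
                raise ValueError("K_d, k_on, k_off are inconsistent (K_d != k_off/k_on)")


@dataclass(frozen=True)
class NetCount:
    """Background-subtracted molecule count with quadrature SD."""

    value: float
    sd: float
    clamped: bool = False


@dataclass(frozen=True)
class QuantResult:
    """Concentration estimate with its provenance chain."""

    n_complex: float
    n_sd: float
    F_total: float        # molecules / s
    F_sd: float
    concentration: float  # molar
    uncertainty: float    # molar


@dataclass(frozen=True)
class CondensateMetrics:
    """Derived condensate-phase quantities (see the condensate helpers)."""

    radius: float                 # m
    phi: float                    # volume fraction
    c_particles: float            # molar
    stoichiometry: float          # probes per particle
    c_probe_in_particles: float   # molar
    c_dense: float                # molar protein in the dense phase
    mass_density: float           # mg/mL
    M_w: float                    # g/mol


# ---------------------------------------------------------------------------
# Counts -> concentration
# ---------------------------------------------------------------------------

def net_count(n_sample: float, sd_sample: float,
              n_control: float, sd_control: float) -> NetCount:
    """Sample minus control count; SDs combined in quadrature.

    A negative difference (control exceeding sample by noise) clamps to 0
    with ``clamped=True`` and a warning rather than raising.
    """
    diff = n_sample - n_control
    sd = math.hypot(sd_sample, sd_control)
    if diff < 0:
        warnings.warn(
            f"control count exceeds sample count ({n_control} > {n_sample}); "
            "net count clamped to 0",
            stacklevel=2,
        )
        return NetCount(value=0.0, sd=sd, clamped=True)
    return NetCount(value=float(diff), sd=float(sd))


def total_flux(n_complex: float, geom: ExperimentGeometry) -> float:
    """Total molecular flux through the device, molecules per second."""
    if n_complex < 0:
        raise ValueError("n_complex must be non-negative")
    return (n_complex / geom.t) * geom.cross_section_factor


def number_concentration(F_total: float, Q_sample: float,
                         recovery_factor: float = 1.0) -> float:
    """Molar concentration from a molecular flux and the sample flow rate.

    ``Q_sample`` is in µL/h.  ``recovery_factor`` rescales for a known
    fraction of analyte retained through upstream sample conditioning
    (e.g. an on-chip desalting module); the default 1.0 applies no
    correction.
    """
    if Q_sample <= 0:
        raise ValueError("Q_sample must be positive")
    if recovery_factor <= 0:
        raise ValueError("recovery_factor must be positive")
    q = Q_sample * _UL_PER_H_TO_L_PER_S
    return F_total / (N_A * q) / recovery_factor


def quantify_counts(net: NetCount, geom: ExperimentGeometry,
                    recovery_factor: float = 1.0) -> QuantResult:
    """Full chain count -> flux -> concentration with linear error propagation."""
    F = total_flux(net.value, geom)
    rel = net.sd / net.value if net.value > 0 else 0.0
    c = number_concentration(F, geom.Q_sample, recovery_factor)
    return QuantResult(
        n_complex=net.value,
        n_sd=net.sd,
        F_total=F,
        F_sd=F * rel,
        concentration=c,
        uncertainty=c * rel,
    )


# ---------------------------------------------------------------------------
# Binding arithmetic
# ---------------------------------------------------------------------------

def target_from_equilibrium(c_complex: float, c_probe_total: float, K_d: float,
                            valency: float = 1.0) -> dict:
    """Back-calculate the target concentration from a 1:1 equilibrium.

    With ``c_free = c_probe_total - valency * c_complex`` the free-target
    concentration follows from mass action,
    ``c_target_free = K_d * c_complex / c_free``, and the total adds back
    the complexed target.  ``valency`` is the mean number of probes per
    target particle (1 for a monovalent analyte).
    """
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    c_free = c_probe_total - valency * c_complex
    if c_free <= 0:
        raise InfeasibleBindingError(
            f"free probe concentration is non-positive ({c_free:g} M); "
            "probe total must exceed valency * complex"
        )
    c_target_free = K_d * c_complex / c_free
    return {
        "c_probe_free": c_free,
        "c_target_free": c_target_free,
        "c_target_total": c_target_free + c_complex,
    }


def binding_site_concentration(c_complex: float, c_free_probe: float, K_d: float) -> float:
    """Total binding-site concentration, ``(c_complex / c_free) * (K_d + c_free)``.

    Valid when the probe is in large excess so that its free concentration
    is well determined; the result counts occupied plus unoccupied sites.
    """
    if c_free_probe <= 0:
        raise ValueError("c_free_probe must be positive")
    return (c_complex / c_free_probe) * (K_d + c_free_probe)


def sites_per_particle(c_sites: float, c_particles: float) -> float:
    """Apparent binding sites per particle."""
    if c_particles <= 0:
        raise ValueError("c_particles must be positive")
    return c_sites / c_particles


def valency_from_intensities(I_complex_median: float, I_free_median: float) -> float:
    """Mean probes bound per particle from the ratio of median burst intensities."""
    if I_free_median <= 0:
        raise ValueError("I_free_median must be positive")
    return I_complex_median / I_free_median


# ---------------------------------------------------------------------------
# Condensates
# ---------------------------------------------------------------------------

def condensate_volume_fraction(c_particles: float, radius: float) -> float:
    """Volume fraction of spherical particles, ``phi = c * N_A * (4/3) pi r^3``.

    ``c_particles`` in molar, ``radius`` in metres.  A result above 1 is
    unphysical and triggers a warning (the value is returned unclipped so
    the caller can see how far off it is).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if c_particles < 0:
        raise ValueError("c_particles must be non-negative")
    per_m3 = c_particles * 1e3 * N_A  # mol/L -> particles per m^3
    phi = per_m3 * (4.0 / 3.0) * math.pi * radius**3
    if phi > 1:
        warnings.warn(f"volume fraction {phi:.3g} exceeds 1 (unphysical)", stacklevel=2)
    return phi


def dense_phase_concentration(c_species_in_particles: float, phi: float,
                              M_w: float) -> dict:
    """Dense-phase molar concentration and mass density.

    ``c_species_in_particles`` is the species concentration referred to
    the total sample volume; dividing by the particle volume fraction
    gives the concentration inside the dense phase.  ``mass_density`` is
    ``c_dense * M_w`` (molar × g/mol = g/L ≡ mg/mL).
    """
    if not (0 < phi <= 1):
        raise ValueError("phi must be in (0, 1]")
    if M_w <= 0:
        raise ValueError("M_w must be positive")
    c_dense = c_species_in_particles / phi
    return {"c_dense": c_dense, "mass_density": c_dense * M_w}


def partition_fractions(c_probe_in_particles: float, c_free_probe: float,
                        c_probe_total: float) -> dict:
    """Percent of free and of total probe residing inside particles."""
    if c_free_probe <= 0 or c_probe_total <= 0:
        raise ValueError("denominator concentrations must be positive")
    return {
        "fraction_of_free": 100.0 * c_probe_in_particles / c_free_probe,
        "fraction_of_total": 100.0 * c_probe_in_particles / c_probe_total,
    }


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def concentration_from_scans(scans, burst_params, region, geom: ExperimentGeometry,
                             control_scans=None, recovery_factor: float = 1.0) -> QuantResult:
    """Run the full pipeline: burst search -> assemble -> integrate -> concentration.

    ``scans`` (and optionally ``control_scans``) are iterables of
    :class:`~digisense.electropherogram.ScanSeries`.  Without a control the
    net count is the sample count with its repeat SD.
    """
    from .electropherogram import analyze_scan, assemble, integrate_region

    analyzed = [analyze_scan(s, burst_params) for s in scans]
    sample = integrate_region(assemble(analyzed), region)
    if control_scans is not None:
        analyzed_c = [analyze_scan(s, burst_params) for s in control_scans]
        control = integrate_region(assemble(analyzed_c), region)
        net = net_count(sample["n_mean"], sample["n_sd"],
                        control["n_mean"], control["n_sd"])
    else:
        net = NetCount(value=sample["n_mean"], sd=sample["n_sd"])
    return quantify_counts(net, geom, recovery_factor)
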