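"""Confocal-volume calibration by fluorescence correlation spectroscopy.

A dilute dye of known diffusion coefficient is measured in the confocal
spot; the normalised intensity autocorrelation of the photon trace is
fitted with the single-component 3D diffusion model

    G(tau) = (1/N) * (1 + tau/tau_D)^-1 * (1 + tau/(kappa^2 tau_D))^-1/2

whose amplitude gives the mean occupancy ``N``, whose decay gives the
diffusion time ``tau_D`` and whose tail shape constrains the axial ratio
``kappa = z0 / w0``.  With the lateral e^-2 radius convention
``tau_D = w0^2 / (4 D)``, the fit plus the known ``D`` yield the volume
dimensions ``w0``, ``z0 = kappa * w0`` and
``V_eff = pi^(3/2) * w0^2 * z0``.

No triplet-state term is included; for dyes with appreciable dark-state
flicker the short-lag points should be excluded from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError, FitError
from .phototrace import PhotonTrace

__all__ = ["AcfCurve", "FcsFit", "diffusion_acf", "autocorrelate", "fit_diffusion_model"]


@dataclass(frozen=True)
class AcfCurve:
    """A normalised intensity autocorrelation curve G(tau)."""

    lags: np.ndarray  # seconds, strictly increasing, > 0
    G: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        G = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", G)
        if lags.size != G.size:
            raise ValueError("lags and G must have equal length")
        if lags.size and (np.any(lags <= 0) or np.any(np.diff(lags) <= 0)):
            raise ValueError("lags must be strictly increasing and positive")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag_s": self.lags, "G": self.G})


@dataclass(frozen=True)
class FcsFit:
    """Diffusion-model fit with derived confocal-volume dimensions."""

    N: float        # mean molecules in the volume
    tau_D: float    # s
    kappa: float    # z0 / w0
    D: float        # µm^2/s (input)
    residual_norm: float
    converged: bool

    @property
    def w0(self) -> float:
        """Lateral e^-2 radius, µm (tau_D = w0^2 / 4D)."""
        return float(np.sqrt(4.0 * self.D * self.tau_D))

    @property
    def z0(self) -> float:
        """Axial e^-2 radius, µm."""
        return self.kappa * self.w0

    @property
    def V_eff(self) -> float:
        """Effective volume pi^(3/2) w0^2 z0, in fL (1 µm^3 = 1 fL)."""
        return float(np.pi**1.5 * self.w0**2 * self.z0)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "tau_D_s": self.tau_D,
            "kappa": self.kappa,
            "D_um2_s": self.D,
            "w0_um": self.w0,
            "z0_um": self.z0,
            "V_eff_fL": self.V_eff,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
        }


def diffusion_acf(tau, N: float, tau_D: float, kappa: float):
    """Single-component 3D diffusion autocorrelation model."""
    tau = np.asarray(tau, dtype=float)
    return (1.0 / N) / (1.0 + tau / tau_D) / np.sqrt(1.0 + tau / (kappa**2 * tau_D))


def autocorrelate(trace: PhotonTrace, lag_grid, min_bin_width: float = 1e-7,
                  bins_per_lag: int = 16) -> AcfCurve:
    """Normalised intensity autocorrelation of a photon trace.

    A multi-tau scheme: for each requested lag the trace is binned at
    ``lag / bins_per_lag`` (floored at ``min_bin_width``) and the
    symmetric-normalisation estimator

        G(tau) = <n_i n_{i+k}> / (<n_i> <n_{i+k}>) - 1

    is evaluated at shift ``k = round(tau / bin)``.  Coarser bins at longer
    lags keep the cost near-linear in trace length while holding the
    relative lag resolution fixed.
    """
    if trace.n_photons < 100:
        raise DataError("at least 100 photons are required for a correlation curve")
    lags = np.asarray(lag_grid, dtype=float)
    times = trace.times_s
    duration = trace.duration
    G = np.empty(lags.size, dtype=float)
    for j, lag in enumerate(lags):
        w = max(lag / bins_per_lag, min_bin_width)
        k = max(int(round(lag / w)), 1)
        n_bins = int(np.ceil(duration / w))
        idx = np.minimum((times / w).astype(np.int64), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        a = counts[:-k]
        b = counts[k:]
        ma = a.mean()
        mb = b.mean()
        if ma == 0 or mb == 0:
            G[j] = 0.0
        else:
            G[j] = float(np.dot(a, b) / a.size / (ma * mb) - 1.0)
    return AcfCurve(lags=lags, G=G)


def fit_diffusion_model(acf: AcfCurve, D: float, kappa_init: float = 5.0,
                        weighting: str = "relative",
                        kappa_fixed: Optional[float] = None) -> FcsFit:
    """Least-squares fit of the 3D diffusion model to a correlation curve.

    ``D`` (µm²/s) is the dye's known diffusion coefficient used only to
    convert the fitted ``tau_D`` into physical volume dimensions.  The fit
    itself is scale-equivariant: rescaling G changes only ``N``.

    ``weighting="relative"`` (default) minimises relative residuals, the
    right choice for correlation noise that scales with G itself and what
    keeps the weakly-identified axial ratio well conditioned; pass
    ``"uniform"`` for plain least squares.

    ``kappa_fixed`` pins the axial ratio (standard practice when the curve
    is too noisy to constrain it) and fits only ``N`` and ``tau_D``.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    lags = acf.lags
    G = acf.G
    if lags.size < 4:
        raise ValueError("at least 4 lag points are required")
    g0 = max(G[0], 1e-12)
    N0 = 1.0 / g0
    # lag at which G falls to half its first value, as tau_D start
    half = g0 / 2
    below = np.flatnonzero(G <= half)
    tau0 = lags[below[0]] if below.size else lags[lags.size // 2]
    if weighting == "relative":
        sigma = np.maximum(np.abs(G), 1e-12 * g0)
    elif weighting == "uniform":
        sigma = None
    else:
        raise ValueError("weighting must be 'relative' or 'uniform'")
    if kappa_fixed is not None:
        model = lambda tau, N, tau_D: diffusion_acf(tau, N, tau_D, kappa_fixed)
        p0 = [N0, float(tau0)]
        bounds = ([1e-12, 1e-12], [np.inf, np.inf])
    else:
        model = diffusion_acf
        p0 = [N0, float(tau0), kappa_init]
        bounds = ([1e-12, 1e-12, 0.1], [np.inf, np.inf, 1e4])
    try:
        popt, _ = curve_fit(model, lags, G, p0=p0, sigma=sigma, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as exc:
        resid = G - model(lags, *p0)
        raise FitError(
            f"diffusion-model fit did not converge (start residual norm "
            f"{np.linalg.norm(resid):.3g}): {exc}"
        ) from exc
    if kappa_fixed is not None:
        N, tau_D = (float(v) for v in popt)
        kappa = float(kappa_fixed)
    else:
        N, tau_D, kappa = (float(v) for v in popt)
    resid = G - diffusion_acf(lags, N, tau_D, kappa)
    return FcsFit(
        N=N, tau_D=tau_D, kappa=kappa, D=D,
        residual_norm=float(np.linalg.norm(resid)), converged=True,
    )
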