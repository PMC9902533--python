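"""Equilibrium and kinetics of the 1:1 probe–analyte reaction P + A <-> PA.

Mass action at equilibrium gives ``K_d * [PA] = [P][A]`` with the two
conservation laws ``[P] + [PA] = P_total`` and ``[A] + [PA] = A_total``,
a quadratic in the complex concentration.  :func:`solve_equilibrium`
solves it in a numerically stable dual-branch form so mass action holds
to ~1e-12 relative even in the quantitative-binding limit (K_d many
orders of magnitude below the totals), where the naive root suffers
catastrophic cancellation.

The excess-probe speciation curve and the post-washout dissociation
decay ``exp(-k_off t)`` complete the small simulator used to reason
about probe affinity and assay timescales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import BindingModel

__all__ = [
    "SpeciationCurve",
    "solve_equilibrium",
    "fraction_bound_excess_probe",
    "speciation_curve",
    "dissociation_survival",
]


@dataclass(frozen=True)
class SpeciationCurve:
    """Fraction of analyte bound versus probe concentration at fixed K_d."""

    probe_concentrations: np.ndarray
    fraction_bound: np.ndarray
    K_d: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probe_concentrations, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        object.__setattr__(self, "probe_concentrations", p)
        object.__setattr__(self, "fraction_bound", f)
        if np.any((f < 0) | (f > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"c_probe_M": self.probe_concentrations, "fraction_bound": self.fraction_bound}
        )


def solve_equilibrium(P_total, A_total, K_d):
    """Equilibrium speciation of P + A <-> PA.

    Parameters are molar and may be scalars or broadcastable arrays;
    ``K_d`` must be positive.  Returns a dict with ``P_free``, ``A_free``
    and ``PA``.

    The complex concentration is the physical root of
    ``PA^2 - (P + A + K_d) PA + P A = 0``.  Two algebraically equivalent
    stable forms are evaluated — the product form for the complex,
    ``PA = 2 P A / (b + sqrt(b^2 - 4 P A))`` with ``b = P + A + K_d``, and
    the analogous form for the free probe — and whichever species is the
    smaller (hence cancellation-prone) quantity is taken from its own
    stable expression.
    """
    P = np.asarray(P_total, dtype=float)
    A = np.asarray(A_total, dtype=float)
    Kd = np.asarray(K_d, dtype=float)
    if np.any(P < 0) or np.any(A < 0):
        raise ValueError("totals must be non-negative")
    if np.any(Kd <= 0):
        raise ValueError("K_d must be positive")

    b = P + A + Kd
    # stable smaller-root form for PA (exact when binding is weak, PA small)
    pa = 2 * P * A / (b + np.sqrt(b * b - 4 * P * A))
    # stable form for P_free from its own quadratic
    # P_free^2 + (A - P + K_d) P_free - K_d P = 0
    beta = A - P + Kd
    p_free = 2 * Kd * P / (beta + np.sqrt(beta * beta + 4 * Kd * P))
    # and for A_free symmetrically
    gamma = P - A + Kd
    a_free = 2 * Kd * A / (gamma + np.sqrt(gamma * gamma + 4 * Kd * A))

    # choose the branch in which the derived (subtracted) quantities are
    # the large, well-conditioned ones
    use_pa = pa <= np.minimum(p_free, a_free)
    PA = np.where(use_pa, pa, np.where(p_free <= a_free, P - p_free, A - a_free))
    P_free = np.where(use_pa, P - pa, np.where(p_free <= a_free, p_free, P - (A - a_free)))
    A_free = np.where(use_pa, A - pa, np.where(p_free <= a_free, A - (P - p_free), a_free))

    if np.ndim(P_total) == 0 and np.ndim(A_total) == 0 and np.ndim(K_d) == 0:
        return {"P_free": float(P_free), "A_free": float(A_free), "PA": float(PA)}
    return {"P_free": P_free, "A_free": A_free, "PA": PA}


def fraction_bound_excess_probe(c_probe, K_d: float):
    """Bound-analyte fraction in the excess-probe limit, ``c / (c + K_d)``."""
    c = np.asarray(c_probe, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_probe must be non-negative")
    f = c / (c + K_d)
    return float(f) if np.ndim(c_probe) == 0 else f


def speciation_curve(probe_grid, K_d: float) -> SpeciationCurve:
    """Excess-probe speciation curve over a probe-concentration grid."""
    grid = np.asarray(probe_grid, dtype=float)
    return SpeciationCurve(
        probe_concentrations=grid,
        fraction_bound=fraction_bound_excess_probe(grid, K_d),
        K_d=K_d,
    )


def dissociation_survival(t, model: BindingModel):
    """Surviving complex fraction ``exp(-k_off t)`` after washout.

    Assumes excess free reagents are removed instantaneously and
    irreversibly (no rebinding), so the complex decays as a pure
    first-order process with ``k_off = K_d * k_on``.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be non-negative")
    s = np.exp(-model.k_off * tt)
    return float(s) if np.ndim(t) == 0 else s
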