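"""Exception hierarchy.

All package-specific failures derive from :class:`DigisenseError` so callers
can catch one base class; plain ``ValueError`` is reserved for malformed
arguments (negative widths, non-positive thresholds and the like).
"""


class DigisenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DigisenseError):
    """Missing or inconsistent metadata / configuration (e.g. no tick resolution)."""


class DataError(DigisenseError):
    """Malformed measurement data (e.g. non-monotone photon timestamps)."""


class AlignmentError(DigisenseError):
    """Scan repeats whose position grids do not match."""


class RegionError(DigisenseError):
    """An integration region that overlaps no scan position."""


class FitError(DigisenseError):
    """A nonlinear fit that failed to converge; carries diagnostics in args."""


class InfeasibleBindingError(DigisenseError):
    """Equilibrium inputs that admit no physical solution (e.g. free probe <= 0)."""
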