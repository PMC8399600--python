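"""Exception hierarchy for the nirtpc pipeline.

All errors raised by the package derive from :class:`NirTpcError`, so
callers (and the CLI) can catch pipeline failures in one place while
still distinguishing the stage that failed.
"""


class NirTpcError(ValueError):
    """Base class for all nirtpc errors."""


class FormatError(NirTpcError):
    """Malformed input file: wrong columns, non-numeric values, row mismatch."""


class GridError(NirTpcError):
    """Invalid wavenumber grid (non-monotonic or non-uniform spacing)."""


class RegionError(NirTpcError):
    """Region selection is invalid or selects no wavenumbers."""


class MetadataError(NirTpcError):
    """Sample metadata violates an invariant (e.g. conflicting concentrations)."""


class ParameterError(NirTpcError):
    """An operator parameter is out of its admissible range."""


class DegenerateDataError(NirTpcError):
    """Data without the variability an operator requires (constant spectrum,
    zero-variance target, zero coefficient vector)."""


class DesignError(NirTpcError):
    """A study design that cannot support the requested computation."""


class ConvergenceError(NirTpcError):
    """Iterative algorithm failed to converge."""


class ConsistencyError(NirTpcError):
    """Physically inconsistent inputs (e.g. equilibrium above initial
    concentration, titration volume not exceeding the blank)."""
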