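"""Exception hierarchy.

Two broad families matter to callers (and to the CLI exit codes):
``ValidationError`` for bad inputs/configuration detected before any heavy
compute, and ``ComputeError`` for failures arising during analysis.
"""


class MemfluctError(Exception):
    """Base class for all package errors."""


class ValidationError(MemfluctError):
    """Invalid parameters, sizes or configuration (pre-compute)."""


class ParameterError(ValidationError):
    """A physical parameter is out of its admissible range."""


class SizeError(ValidationError):
    """An input is too small (grid, point set, series ...)."""


class ConfigurationError(ValidationError):
    """Inconsistent run configuration (e.g. q_max beyond Nyquist)."""


class ComputeError(MemfluctError):
    """A failure during analysis of otherwise valid inputs."""


class AmbiguousLeafletError(ComputeError):
    """Marker z-populations cannot be split into two leaflets."""


class InvertedLeafletError(ComputeError):
    """Upper surface dips below the lower one (non-physical thickness)."""


class InsufficientDataError(ComputeError):
    """Too few shells/points/frames for the requested fit."""


class FitError(ComputeError):
    """A least-squares fit failed or returned a non-physical result."""


class UndefinedInefficiencyError(ComputeError):
    """Statistical inefficiency undefined (zero-variance series)."""
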