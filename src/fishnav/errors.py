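"""Exception hierarchy.

All errors derive from :class:`FishnavError` so callers can trap the whole
family; pipeline code additionally distinguishes validation problems (bad
input data) from contract violations (caller bugs).
"""


class FishnavError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FishnavError):
    """Unknown strategy/displacement key or an invalid arena configuration."""


class GeometryError(FishnavError):
    """A constructed position or polyline falls outside the tank."""


class ValidationError(FishnavError):
    """Malformed input data (CSV structure, time ordering, coordinates)."""


class DegenerateTrajectoryError(FishnavError):
    """A path too short or too degenerate for the requested operation."""


class DegenerateAngleError(FishnavError):
    """Angle requested for a zero-length displacement."""


class UndefinedMeanError(FishnavError):
    """Circular mean of a perfectly balanced axial sample."""


class InsufficientSampleError(FishnavError):
    """Too few observations for the requested test."""


class ContractError(FishnavError):
    """Caller violated a documented precondition."""


class NoAnalysableTrialsError(FishnavError):
    """Every trial in a pipeline run failed validation or cropping."""
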