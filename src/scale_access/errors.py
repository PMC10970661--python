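"""Typed errors raised by validation and pipeline stages.

Every malformed input raises one of these; data is never silently dropped.
"""


class ScaleAccessError(ValueError):
    """Base class for all package errors."""


class SchemaError(ScaleAccessError):
    """A required field is missing, duplicated, or violates an invariant."""


class CoordinateSystemError(ScaleAccessError):
    """Coordinates look like lon/lat degrees instead of planar meters."""


class NetworkError(ScaleAccessError):
    """Road-network input is empty, inconsistent, or disconnected."""


class UnreachableError(ScaleAccessError):
    """An origin-destination pair has no path and unreachable pairs are not allowed."""


class DegenerateInputError(ScaleAccessError):
    """An input carries no usable information (e.g. a constant score vector)."""
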