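"""Exception hierarchy shared across the package.

Parameter/usage problems derive from :class:`ParameterError` (a
``ValueError``); problems with the data itself (degenerate inputs,
unreadable files) derive from :class:`DataError` (a ``RuntimeError``).
The CLI maps the two branches to distinct exit codes.
"""


class FlimQCError(Exception):
    """Base class for all package errors."""


class ParameterError(FlimQCError, ValueError):
    """A parameter is outside its documented domain."""


class DimensionError(ParameterError):
    """Array shapes of co-registered inputs do not match."""


class DataError(FlimQCError, RuntimeError):
    """Input data cannot be processed (degenerate or malformed)."""


class FormatError(DataError):
    """A file does not match the expected on-disk format."""


class DegenerateReferenceError(DataError):
    """Calibration reference has no usable signal."""


class DegenerateCloudError(DataError):
    """Phasor cloud has too few usable points for the requested summary."""


class DegenerateHistogramError(DataError):
    """Histogram carries no information (e.g. constant image)."""
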