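"""Exception hierarchy.

``FormatError`` covers malformed inputs and column-mapping problems,
``DataError`` covers structurally valid but unusable data, and
``EligibilityError`` is raised when a recording cannot supply the requested
analysis window.  ``ParameterError`` flags invalid configuration values.
"""


class LarcError(Exception):
    """Base class for all package errors."""


class FormatError(LarcError):
    """Input file or column mapping is malformed."""


class DataError(LarcError):
    """Data content is invalid (non-monotonic time, empty file, bad labels)."""


class ParameterError(LarcError, ValueError):
    """A configuration or function parameter is out of range."""


class EligibilityError(LarcError):
    """Recording does not contain enough data for the requested window."""
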