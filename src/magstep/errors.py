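"""Exception hierarchy.

All validation failures derive from :class:`ValidationError` so that the CLI
can map them to a single exit code (2).
"""


class MagstepError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MagstepError, ValueError):
    """Invalid input data, configuration, or parameters."""


class InvalidGeometryError(ValidationError):
    """Non-positive side length or otherwise unusable device geometry."""


class TriangleViolationError(ValidationError):
    """Distance triple violates the triangle inequality beyond tolerance."""


class InsufficientDataError(ValidationError):
    """Too few samples or events for the requested computation."""
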