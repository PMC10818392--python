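"""Exception hierarchy.

Every error raised by the library derives from :class:`PosturoKitError`
so callers can catch library failures with a single except clause.
"""


class PosturoKitError(Exception):
    """Base class for all posturokit errors."""


class SchemaError(PosturoKitError):
    """Input file or payload does not conform to the documented schema."""


class ValidationError(PosturoKitError):
    """A domain-type invariant is violated (e.g. non-monotone timestamps)."""


class ParseError(PosturoKitError):
    """A cell or field could not be parsed as the expected type."""


class ParameterError(PosturoKitError):
    """A function parameter is outside its valid range."""


class InsufficientDataError(PosturoKitError):
    """Too few samples to compute the requested quantity."""


class ProtocolError(PosturoKitError):
    """A test protocol constraint is violated (trial count, duration...)."""


class GeometryError(PosturoKitError):
    """Degenerate geometry (zero-length ray, coincident points)."""


class GenerationError(PosturoKitError):
    """A synthetic-data request is infeasible."""


class ComparisonError(PosturoKitError):
    """Two results cannot be compared (e.g. different configurations)."""
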