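"""Exception hierarchy shared across the package."""


class UnfoldkitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(UnfoldkitError):
    """A file could not be parsed in the expected format."""


class EmptyStructureError(FormatError):
    """A structure file contained no protein atoms after filtering."""


class TopologyError(UnfoldkitError):
    """Trajectory frames do not match the supplied topology."""


class DomainConfigError(UnfoldkitError):
    """A domain-partition configuration failed validation."""


class GeometryError(UnfoldkitError):
    """Coordinates are degenerate for the requested operation."""


class ParameterError(UnfoldkitError):
    """An operation was called with an out-of-range parameter."""


class AnalysisError(UnfoldkitError):
    """A pipeline stage failed; carries stage/frame context in the message."""
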