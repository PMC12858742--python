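"""Exception hierarchy shared across the toolkit."""


class BedsynthError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(BedsynthError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(BedsynthError, ValueError):
    """A configuration file / preset / palette is invalid."""


class GeometryError(BedsynthError, ValueError):
    """Degenerate geometry (zero-length bone, empty region, ...)."""


class FormatError(BedsynthError, ValueError):
    """A file does not conform to its documented schema."""


class PlacementError(BedsynthError, RuntimeError):
    """No feasible sprite placement found within the retry budget."""


class AlignmentError(BedsynthError, ValueError):
    """Paired inputs cannot be index-aligned."""
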