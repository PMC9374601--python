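"""Exception hierarchy shared by all eyeuse modules."""


class EyeUseError(Exception):
    """Base class for all errors raised by eyeuse."""


class FormatError(EyeUseError):
    """An input file does not have the expected structure."""


class ParseError(FormatError):
    """A cell that should be numeric could not be parsed."""


class ValidationError(EyeUseError):
    """A value violates a documented invariant (range, sum, ordering)."""


class GeometryError(EyeUseError):
    """Degenerate head or stimulus geometry (coincident points, origin
    inside a stimulus, undefined angles)."""


class ConsistencyError(EyeUseError):
    """Two objects that must describe the same frames do not."""


class InsufficientDataError(EyeUseError):
    """Too few frames to compute the requested statistic."""
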