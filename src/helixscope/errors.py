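"""Exception hierarchy shared by all helixscope modules."""


class HelixscopeError(Exception):
    """Base class for all package errors."""


class FormatError(HelixscopeError):
    """A file could not be parsed as its declared format."""


class InconsistencyError(HelixscopeError):
    """Structurally valid input that contradicts itself or the topology."""


class TruncatedFileError(FormatError):
    """A binary trajectory ended mid-frame.

    Attributes
    ----------
    complete_frames : int
        Number of frames that were fully read before truncation.
    """

    def __init__(self, message: str, complete_frames: int):
        super().__init__(message)
        self.complete_frames = complete_frames


class SelectionSyntaxError(HelixscopeError):
    """Selection expression failed to parse.

    Carries ``position``, the character offset of the offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EmptySelectionError(HelixscopeError):
    """An operation that requires atoms received an empty selection."""


class DegenerateGeometryError(HelixscopeError):
    """Point set too degenerate for the requested geometric operation."""


class ParameterAssignmentError(HelixscopeError):
    """One or more atoms had no matching row in a parameter table."""

    def __init__(self, message: str, unmatched: list):
        super().__init__(message)
        self.unmatched = unmatched


class ConfigError(HelixscopeError):
    """Invalid analysis configuration."""
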