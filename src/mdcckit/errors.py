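"""Exception hierarchy for mdcckit."""


class MdccKitError(Exception):
    """Base class for all mdcckit errors."""


class FormatError(MdccKitError):
    """A file could not be parsed as the named standard format."""


class ValidationError(MdccKitError):
    """Parsed data violates a structural invariant (e.g. duplicate atom identity)."""


class ShapeError(MdccKitError):
    """Frame/atom dimensions are inconsistent.

    Attributes
    ----------
    frame : int or None
        1-based index of the offending frame, when known.
    """

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


class SelectionError(MdccKitError):
    """An atom-selection expression is malformed or selects nothing."""


class DegenerateFitError(MdccKitError):
    """Rigid-body superposition is underdetermined (<3 atoms or collinear)."""


class AtomLookupError(MdccKitError, KeyError):
    """An atom or mode index does not exist."""


class ParameterError(MdccKitError, ValueError):
    """A parameter is outside its admissible range."""


class UndefinedCorrelationError(MdccKitError):
    """A correlation is undefined (zero variance / zero weighted variance)."""


class ChainSpecError(MdccKitError):
    """A synthetic allosteric-chain specification is internally inconsistent."""
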