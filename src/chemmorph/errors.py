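"""Exception and warning hierarchy for chemmorph.

All library errors derive from :class:`ChemmorphError` so callers can catch
one base class; the CLI maps subclasses onto exit codes.
"""


class ChemmorphError(Exception):
    """Base class for all chemmorph errors."""


class CapacityError(ChemmorphError):
    """A drawing would exceed the hard atom capacity (100000 atoms)."""


class DuplicateIdError(ChemmorphError):
    """An atom id is already present in the drawing."""


class DanglingBondError(ChemmorphError):
    """A bond endpoint references an atom id absent from the drawing."""


class SelfBondError(ChemmorphError):
    """A bond joins an atom to itself."""


class EmptyDrawingError(ChemmorphError):
    """An operation that needs at least one atom got an empty drawing."""


class FormatError(ChemmorphError):
    """Malformed molfile or scene-file content."""


class UnsupportedVersionError(FormatError):
    """A molfile declares a connection-table version other than V2000."""


class DegenerateError(ChemmorphError):
    """Collinear/degenerate control points cannot determine a mapping."""


class HorizonError(ChemmorphError):
    """A projective map was evaluated on (numerically) the line at infinity."""


class DomainError(ChemmorphError):
    """A numeric argument lies outside its documented domain."""


class CorrespondenceError(ChemmorphError):
    """A correspondence references atoms/bonds absent from its drawings."""


class ChainError(ChemmorphError):
    """Consecutive morph steps do not share their junction drawing."""


class TopologyError(ChemmorphError):
    """A molecule does not have the connectivity a preset requires."""


class EmptyInputError(ChemmorphError):
    """A non-empty list of frames/rasters was required."""


class CompatibilityWarning(UserWarning):
    """Molfile export exceeds the 999-atom/999-bond V2000 record limit.

    Carried as a value (not raised) in the writer's warning list so callers
    can log or assert on it. ``code`` is machine readable.
    """

    def __init__(self, code: str, message: str) -> None:
        super().__init__(message)
        self.code = code
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CompatibilityWarning(code={self.code!r}, message={self.message!r})"
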