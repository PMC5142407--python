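"""Exception hierarchy.

Every error raised by the library derives from :class:`PepGCMError`, so
callers (and the CLI) can catch one type.
"""


class PepGCMError(Exception):
    """Base class for all pepgcm errors."""


class ParameterError(PepGCMError):
    """Invalid, missing or inconsistent model parameters."""


class UnknownResidueError(PepGCMError):
    """A symbol outside the twenty standard one-letter amino-acid codes."""

    def __init__(self, code: str, position: int | None = None):
        self.code = code
        self.position = position
        where = "" if position is None else f" at position {position + 1}"
        super().__init__(f"unknown residue symbol {code!r}{where}")


class SequenceTooShortError(PepGCMError):
    """Sequence shorter than the two residues the neighbour rule needs."""


class EmptyDatasetError(PepGCMError):
    """An operation received no records to work on."""


class DomainError(PepGCMError):
    """Numeric argument outside its mathematical domain."""


class ConvergenceError(PepGCMError):
    """Iterative solver exhausted its budget."""

    def __init__(self, message: str, bracket: tuple[float, float] | None = None):
        self.bracket = bracket
        super().__init__(message)


class UnidentifiableParameterError(PepGCMError):
    """Fit requested for parameters the data never observes."""

    def __init__(self, entries):
        self.entries = tuple(entries)
        listed = ", ".join(f"{c}/{cls}" for c, cls in self.entries)
        super().__init__(
            f"{len(self.entries)} alpha parameter(s) have no observations and no "
            f"regularization to constrain them: {listed}"
        )


class FormatError(PepGCMError):
    """Malformed input file."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = "" if path is None else f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
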