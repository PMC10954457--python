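"""Exception hierarchy.

Parse-time problems raise :class:`FormatError` (CLI exit code 3); violated
analysis preconditions raise :class:`AnalysisError` (exit code 4).
"""


class ProbescapeError(Exception):
    """Base class for all package errors."""


class RegistryError(ProbescapeError, KeyError):
    """Unknown format tag or plot kind; message lists the valid tags."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class FormatError(ProbescapeError, ValueError):
    """A file violated its format contract (names file, line and rule)."""


class AnalysisError(ProbescapeError, ValueError):
    """An analysis precondition was not met."""


class MappingError(ProbescapeError, ValueError):
    """Data and mapping disagree about the underlying sequence."""
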