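"""Exception hierarchy for voteseg.

All toolkit errors derive from :class:`VotesegError` so callers can catch one
base class at a CLI or pipeline boundary.
"""


class VotesegError(Exception):
    """Base class for all voteseg errors."""


class FormatError(VotesegError):
    """A file could not be read or written under the named standard."""


class DimensionalityError(VotesegError):
    """A payload does not have the required number of dimensions."""


class ParameterError(VotesegError, ValueError):
    """An argument violates an operation's contract."""


class ConsistencyError(VotesegError):
    """Aligned objects disagree in shape, geometry, or completeness."""


class SpecError(VotesegError):
    """A model specification is internally inconsistent or incompatible."""


class DataError(VotesegError):
    """Input data is empty or otherwise unusable."""


class VoterLookupError(VotesegError, KeyError):
    """A voting scheme references a voter absent from the prediction set."""


class SchemeError(VotesegError):
    """A voting scheme is structurally invalid (e.g. cyclic nesting)."""


class ConfigError(VotesegError):
    """A phantom / degradation configuration cannot be realised."""


class DegenerateDataError(VotesegError):
    """A statistical routine received data it cannot test (e.g. constant)."""
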