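"""Exception hierarchy for mitocount.

Every error raised on a user-facing code path derives from
:class:`MitoCountError` so the CLI can catch one type and emit a one-line
diagnostic with a nonzero exit code.
"""


class MitoCountError(Exception):
    """Base class for all mitocount errors."""


class ParameterError(MitoCountError, ValueError):
    """A configuration value is out of its documented range."""


class FormatError(MitoCountError, ValueError):
    """Malformed or inconsistent input file."""


class InsufficientCoverageError(MitoCountError):
    """No read in the pool matches an anchor window within tolerance."""

    def __init__(self, anchor: str, message: str | None = None):
        self.anchor = anchor
        super().__init__(
            message
            or f"insufficient mitochondrial coverage: no {anchor} anchor read "
            f"matches the reference window within tolerance"
        )


class AssemblyGapError(MitoCountError):
    """Greedy extension stalled before the ending read was met."""

    def __init__(self, position: int, message: str | None = None):
        self.position = position
        super().__init__(
            message or f"assembly gap: extension stalled at contig position {position}"
        )


class RunawayAssemblyError(MitoCountError):
    """The contig grew past the maximum length without meeting the end anchor."""

    def __init__(self, length: int, max_length: int):
        self.length = length
        self.max_length = max_length
        super().__init__(
            f"runaway assembly: contig length {length} exceeded the maximum "
            f"{max_length} without incorporating the ending read"
        )


class ConsensusError(MitoCountError):
    """The assembled consensus violates one of its invariants."""


class DegenerateInputError(MitoCountError, ValueError):
    """Counts that make the copy-number formula undefined."""
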