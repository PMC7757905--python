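"""Exception types shared across the toolkit."""


class HgcrdError(Exception):
    """Base class for all toolkit errors."""


class ParseError(HgcrdError):
    """A text input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedConductanceError(HgcrdError):
    """Conductance requested for a set whose min-side volume is zero."""


class NoMotifAtSeedError(HgcrdError):
    """The seed node participates in no hyperedge / motif instance."""


class EmptySweepError(HgcrdError):
    """Every sweep prefix had undefined conductance; no cluster can be returned."""


class GenerationError(HgcrdError):
    """A synthetic generator produced a degenerate (empty) instance."""


class ProtocolError(HgcrdError):
    """An evaluation protocol could not be carried out for any seed."""
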