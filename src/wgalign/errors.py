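"""Exception hierarchy shared across the aligner."""


class WgalignError(Exception):
    """Base class for all package errors."""


class MalformedInputError(WgalignError):
    """Input file (FASTA/PAF) violates the format; message carries line context."""


class InvalidInputError(WgalignError):
    """Semantically invalid input (e.g. empty reference genome)."""


class PreconditionError(WgalignError):
    """An operation's documented precondition was violated by the caller."""


class InternalConsistencyError(WgalignError):
    """Pipeline state contradicts itself (e.g. anchor does not match sequences)."""


class BandExceededError(WgalignError):
    """Length difference of an alignment pair exceeds the DP band half-width."""


class InvalidSpecError(WgalignError):
    """A synthetic mutation specification is out of bounds or self-overlapping."""


class WorkerError(WgalignError):
    """A pooled work unit failed; message names the task identifier."""
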