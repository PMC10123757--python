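"""Exception hierarchy for silkmech."""


class SilkmechError(Exception):
    """Base class for all silkmech errors."""


class FormatError(SilkmechError):
    """An input file does not conform to the expected layout."""


class InsufficientDataError(SilkmechError):
    """Too few valid samples to carry out the requested operation."""


class DomainError(SilkmechError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class SegmentationError(SilkmechError):
    """The record cannot be split into loading-unloading cycles."""


class GenerationError(SilkmechError):
    """The synthetic fiber model cannot realise the requested parameters."""

    def __init__(self, message: str, cycle: int | None = None):
        if cycle is not None:
            message = f"cycle {cycle}: {message}"
        super().__init__(message)
        self.cycle = cycle
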