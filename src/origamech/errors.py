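"""Exception hierarchy used across the package."""


class OrigamechError(Exception):
    """Base class for all package errors."""


class FormatError(OrigamechError):
    """A file does not conform to its declared on-disk format."""


class ConsistencyError(OrigamechError):
    """A parsed object violates an internal invariant (dangling links, bad counts)."""


class ArgumentError(OrigamechError, ValueError):
    """Invalid argument combination supplied by the caller."""


class DegeneracyError(OrigamechError):
    """A geometric operation received a degenerate (e.g. collinear) point set."""


class EmptyStructureError(OrigamechError):
    """A structure file contained no usable records."""


class DegenerateHistogramError(OrigamechError):
    """All samples identical; no histogram can be formed."""


class UndefinedCorrelationError(OrigamechError):
    """Pearson correlation undefined (zero variance in one of the vectors)."""


class SiteSkip(OrigamechError):
    """Signal: this frame cannot be scored for this site (e.g. unpaired window)."""


class StageError(OrigamechError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
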