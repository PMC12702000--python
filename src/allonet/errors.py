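"""Exception hierarchy shared across the pipeline stages."""


class AllonetError(Exception):
    """Base class for all package-specific errors."""


class ModelIOError(AllonetError):
    """Unreadable or malformed atomic-model file."""


class InsertionCodeError(ModelIOError):
    """Residue insertion codes are not supported in residue addressing."""


class IncompatibleDatasetsError(AllonetError):
    """Inputs that must share geometry (unit cell / grid) do not."""


class InsufficientOverlapError(AllonetError):
    """Too few common reflections (or peptides) to proceed."""


class ParameterError(AllonetError):
    """A parameter is outside its documented domain."""


class InvariantViolationError(AllonetError):
    """An input violates a documented data invariant."""


class DegeneratePeptideError(AllonetError):
    """Peptide too short or with no exchangeable backbone amides."""


class JoinError(AllonetError):
    """Records that must align on (span, timepoint, ...) do not."""


class SectorParseError(AllonetError):
    """Unparseable residue-set file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
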