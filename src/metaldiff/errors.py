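"""Exception hierarchy for the metaldiff pipeline."""


class MetaldiffError(Exception):
    """Base class for all package errors."""


class ParseError(MetaldiffError):
    """Raised when a PDB file cannot be parsed; names the offending line."""


class EmptyStructureError(MetaldiffError):
    """Raised when a structure has no residues after parsing/cleaning."""


class TooManyResiduesError(MetaldiffError):
    """Raised (rejection flag) when a cleaned structure exceeds the residue cap."""


class ContractError(MetaldiffError):
    """Raised on API contract violations (length mismatch, config-hash mismatch, ...)."""


class DomainError(MetaldiffError, ValueError):
    """Raised when a numeric argument is outside its mathematical domain."""


class GeometryError(MetaldiffError):
    """Raised when synthetic-geometry placement fails after bounded retries."""


class SampleDivergenceError(MetaldiffError):
    """Raised when the reverse sampler encounters non-finite scores."""

    def __init__(self, step: int, message: str = ""):
        self.step = step
        super().__init__(message or f"non-finite score at reverse step {step}")


class TrainingError(MetaldiffError):
    """Raised when training aborts (NaN loss, degenerate labels, empty data)."""
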