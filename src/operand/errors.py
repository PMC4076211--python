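"""Exception hierarchy shared across the package."""


class OperandError(Exception):
    """Base class for all package-specific errors."""


class SeriesTooShortError(OperandError, ValueError):
    """Series has fewer points than an operation requires."""


class DegenerateSeriesError(OperandError, ValueError):
    """Series (or window) has zero spread, so distance-ratio criteria
    and recurrence-rate quantiles are undefined."""


class UndefinedTransitivityError(OperandError, ValueError):
    """Graph contains no length-two paths, so transitivity has no value.

    Distinct from a transitivity of zero (open triples exist but none close).
    """


class TransitivityDomainError(OperandError, ValueError):
    """Transitivity outside (0, 1] has no dimension."""


class OutOfVocabularyError(OperandError, KeyError):
    """Word absent from the co-occurrence model, or has an all-zero row."""


class SpecError(OperandError, ValueError):
    """Infeasible benchmark specification (e.g., overlapping segments)."""
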