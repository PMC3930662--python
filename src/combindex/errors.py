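"""Exception hierarchy for dose-response and combination analysis."""


class CombindexError(Exception):
    """Base class for all package errors."""


class DomainError(CombindexError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class FitInfeasibleError(CombindexError):
    """Too few usable observations (or degenerate doses) to fit a model.

    Carries the excluded observations so callers can report them.
    """

    def __init__(self, message: str, excluded=None):
        super().__init__(message)
        self.excluded = list(excluded) if excluded is not None else []


class ModelInvalidError(CombindexError):
    """A fitted model cannot be used (e.g. non-positive slope makes the
    dose inversion undefined)."""


class UndefinedCIError(CombindexError):
    """Combination index is undefined at this effect level (fa of exactly
    0 or 1 makes the iso-effective doses vanish or diverge)."""
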