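"""Exception hierarchy for literank.

All rejected-input signals raise :class:`InputError`; undefined numeric
results (zero-norm cosine, zero-variance R²) raise
:class:`UndefinedScoreError` so callers can report "missing" rather than a
fake 0.0.
"""

from __future__ import annotations


class LiterankError(Exception):
    """Base class for all literank errors."""


class InputError(LiterankError, ValueError):
    """An input violates a documented precondition."""


class QueryError(InputError):
    """A free-text query contains no dictionary words.

    Carries the unrecognized tokens so the user can rephrase.
    """

    def __init__(self, message: str, unrecognized: tuple[str, ...] = ()):
        super().__init__(message)
        self.unrecognized = tuple(unrecognized)


class UndefinedScoreError(LiterankError, ArithmeticError):
    """A score is mathematically undefined (never silently reported as 0)."""


class FitError(LiterankError, RuntimeError):
    """Tri-modal curve fit failed to converge.

    Carries the best parameters and residual seen so far for diagnostics.
    """

    def __init__(self, message: str, best_params=None, best_residual=None):
        super().__init__(message)
        self.best_params = best_params
        self.best_residual = best_residual


class ThresholdError(LiterankError, RuntimeError):
    """No component intersection exists between adjacent peaks.

    Raised when mixture components overlap too heavily for a data-driven
    cutoff; the recommended fallback is a manual threshold.
    """
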