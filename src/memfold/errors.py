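"""Exception hierarchy shared across modules."""


class MemfoldError(Exception):
    """Base class for all package errors."""


class InputError(MemfoldError, ValueError):
    """Malformed or contract-violating input (wrong lengths, mismatched records, ...)."""


class DomainError(MemfoldError, ValueError):
    """Value outside the mathematical domain of an operation (e.g. K_D <= 0)."""


class DegenerateInputError(MemfoldError, ValueError):
    """Input that makes the requested statistic undefined (zero variance, collinear groups)."""


class FitConvergenceError(MemfoldError, RuntimeError):
    """Nonlinear fit failed to converge.

    Carries the best parameter set seen so far in ``best_params`` so callers
    can inspect or restart.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params


class FitDiagnosticError(MemfoldError, RuntimeError):
    """Fit is formally converged but scientifically unresolvable.

    Used e.g. when a three-state titration cannot resolve the intermediate;
    the message suggests the appropriate fallback, never switching silently.
    """

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params
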