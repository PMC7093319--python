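"""Exception hierarchy shared across the pipeline stages."""


class PrsnetError(Exception):
    """Base class for all package errors."""


class InputError(PrsnetError, ValueError):
    """Invalid argument to an operation (unknown node, bad matrix, ...)."""


class ConstructionError(PrsnetError):
    """A planted network could not be made positive definite."""


class EstimationError(PrsnetError):
    """Correlation or network estimation failed (constant column, too few
    complete observations, non-PSD input)."""


class ConvergenceError(EstimationError):
    """Constrained maximum-likelihood fit did not reach the requested
    tolerance; carries diagnostics."""

    def __init__(self, message: str, *, n_iter: int | None = None,
                 violation: float | None = None):
        super().__init__(message)
        self.n_iter = n_iter
        self.violation = violation


class DataValidationError(PrsnetError, ValueError):
    """A dataset file violates the declared column schema."""


class MissingColumnError(DataValidationError):
    """A declared column is absent from the file."""


class ConfigError(PrsnetError, ValueError):
    """Pipeline configuration invalid; lists every violation found."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid configuration:\n" + "\n".join(f"- {v}" for v in self.violations)
        )
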