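"""Exception hierarchy shared across the package.

The pipeline maps these onto process exit codes: validation problems -> 2,
optimizer non-convergence -> 3, missing upstream artifacts -> 4.
"""


class ShellrankError(Exception):
    """Base class for all package errors."""


class SchemaError(ShellrankError):
    """A required column is missing or mis-typed."""


class ValidationError(ShellrankError):
    """A row violates a data invariant (range, uniqueness, ...)."""


class DegeneratePredictorError(ShellrankError):
    """A predictor has zero variance and cannot be standardized."""


class AliasingError(ShellrankError):
    """The fixed-effects design is rank deficient."""


class ConvergenceError(ShellrankError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class NestingError(ShellrankError):
    """Likelihood-ratio comparison of non-nested models."""


class ProcedureError(ShellrankError):
    """A multi-stage procedure failed (e.g. too many randomized refits diverged)."""


class DependencyError(ShellrankError):
    """A pipeline stage is missing an upstream artifact."""
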