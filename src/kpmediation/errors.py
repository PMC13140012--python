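"""Exception hierarchy shared across the package.

The split mirrors how failures are handled downstream: schema/contract
errors are programming or configuration mistakes and abort immediately;
validation/integrity errors point at offending rows of an input file;
domain errors flag mathematically invalid values (zero denominators,
non-PSD covariances); fit errors carry model diagnostics.
"""

from __future__ import annotations


class KPMediationError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KPMediationError):
    """A required column is absent or a schema entry is malformed."""


class ValidationError(KPMediationError):
    """A cell value violates its schema (bounds, categorical levels)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class IntegrityError(KPMediationError):
    """Structural violation, e.g. duplicated (subject, visit) records."""


class ContractError(KPMediationError, ValueError):
    """A function was called outside its documented precondition."""


class DomainError(KPMediationError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class SingularFitError(KPMediationError):
    """Design matrix is rank deficient; names the aliased columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(
            "design matrix is rank deficient; aliased terms: "
            + ", ".join(self.aliased)
        )


class ConvergenceError(KPMediationError):
    """Model fitting failed to converge; carries last-iterate diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
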