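"""Exception hierarchy.

Three broad families map onto distinct CLI exit codes: input/contract
problems (exit 2), model-fitting failures (exit 3), and parameter/domain
violations of closed-form formulas (exit 4).
"""


class CaseOnlyError(Exception):
    """Base class for all package errors."""


class InputError(CaseOnlyError):
    """Malformed files, missing columns, schema violations. CLI exit 2."""


class InvalidTableError(InputError):
    """A count table violates its invariants (negative cell, zero margin)."""


class ZeroCellError(InvalidTableError):
    """A cell required in a denominator or variance is zero.

    Carries the offending cell name so callers can report it.
    """

    def __init__(self, cell: str, message: str | None = None):
        self.cell = cell
        super().__init__(message or f"cell '{cell}' is zero; enable the continuity "
                                    f"correction or supply a nonzero count")


class DegenerateReferenceError(InvalidTableError):
    """The S-E- reference stratum has no cases, so relative risks are undefined."""


class ContractViolationError(InputError):
    """Data handed to an operation violates its stated precondition
    (e.g. non-cases passed to the case-only estimator)."""


class FitError(CaseOnlyError):
    """Regression failure: non-convergence, separation, collinearity. CLI exit 3."""


class ParameterError(CaseOnlyError):
    """A numeric argument is outside its admissible range. CLI exit 4."""


class DomainError(ParameterError):
    """Closed-form expression undefined for these inputs
    (e.g. 1/p0 not exceeding every relative risk in the sensitivity formula)."""
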