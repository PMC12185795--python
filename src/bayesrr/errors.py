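"""Exception types shared across the package."""


class BayesRRError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BayesRRError):
    """A cohort CSV header does not match the documented schema."""


class CohortValidationError(BayesRRError):
    """A cohort row violates a record invariant (range, coding)."""


class DegenerateCohortError(BayesRRError):
    """An operation requires both age groups but one is absent."""


class UndefinedTestError(BayesRRError):
    """A contingency-table test is undefined (zero margin, empty sample)."""


class DegenerateDesignError(BayesRRError):
    """A design matrix is unusable (constant exposure, rank deficiency)."""


class NonConvergenceError(BayesRRError):
    """Iterative fitting failed to converge; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class OracleInapplicableError(BayesRRError):
    """The closed-form two-group posterior approximation is undefined."""


class MixingFailureError(BayesRRError):
    """An MCMC chain rejected essentially every proposal during burn-in."""


class DegenerateChainError(BayesRRError):
    """A chain has zero variance; convergence diagnostics are undefined."""


class ConvergenceError(BayesRRError):
    """Summaries refused because the convergence gate failed."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
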