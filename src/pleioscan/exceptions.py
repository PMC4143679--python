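"""Exception hierarchy shared across the package."""


class PleioscanError(Exception):
    """Base class for all package-specific errors."""


class MonomorphicError(PleioscanError):
    """Raised when a SNP carries only one allele in the analysed sample.

    The intercept-only binomial MLE sits on the boundary of the parameter
    space (p-hat of 0 or 1) and no association test is defined; QC should
    normally remove such SNPs before they reach the model.
    """


class DegenerateDesignError(PleioscanError):
    """Raised when the phenotype design matrix is rank deficient.

    Typically a constant phenotype column collinear with the intercept, or a
    singular Fisher information matrix during Newton iterations.
    """


class DomainError(PleioscanError):
    """Raised when a value falls outside the mathematical domain of a step
    (e.g. a non-positive blood-pressure reading fed to the log transform)."""


class InsufficientDataError(PleioscanError):
    """Raised when too few observations exist to estimate a parameter
    (e.g. a phenotype column observed for fewer than two individuals)."""
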