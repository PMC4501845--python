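"""Exception hierarchy for mitovar.

All package-specific errors derive from :class:`MitovarError` so callers can
catch a single base class at pipeline boundaries.
"""


class MitovarError(Exception):
    """Base class for all mitovar errors."""


class InvalidInputError(MitovarError, ValueError):
    """An argument is outside its documented domain (bad coordinate, negative
    Phred score, empty region set, ...)."""


class ContractError(MitovarError, ValueError):
    """An internal consistency requirement between two arguments is violated,
    e.g. allele fractions that do not match the genotype they are paired with,
    or a prior that is not a probability distribution."""


class NoDataError(MitovarError):
    """An operation that needs at least one observation received none."""


class OptimizationError(MitovarError):
    """Allele-fraction maximisation failed to converge.

    Carries the best point found so the caller can decide whether to use it.
    """

    def __init__(self, message, best_fractions=None, best_log_likelihood=None):
        super().__init__(message)
        self.best_fractions = best_fractions
        self.best_log_likelihood = best_log_likelihood


class DegenerateFitError(MitovarError):
    """A regression model cannot be identified from the data supplied
    (all-zero counts, constant covariate, ...)."""
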