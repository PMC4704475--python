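"""Exception hierarchy for fcgwas."""


class FcgwasError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FcgwasError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateGenotypeError(FcgwasError, ValueError):
    """The genotype vector is monomorphic: no association is identifiable."""


class DegeneratePhenotypeError(FcgwasError, ValueError):
    """A phenotype column has zero variance."""


class InsufficientSampleError(FcgwasError, ValueError):
    """Fewer subjects than the method requires (bias correction needs n >= 4)."""


class ConvergenceError(FcgwasError, RuntimeError):
    """An iterative fit did not converge within its iteration budget."""


class SingularMatrixError(FcgwasError, ValueError):
    """A covariance/SSCP matrix required to be invertible is singular."""


class ParseError(FcgwasError, ValueError):
    """A data file could not be parsed."""
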