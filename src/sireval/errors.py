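"""Exception types shared across the package."""


class SirevalError(Exception):
    """Base class for all package-specific errors."""


class InvalidDesignError(SirevalError, ValueError):
    """A simulation design violates its invariants (counts, allocation)."""


class PedigreeCycleError(SirevalError, ValueError):
    """An animal is its own ancestor."""


class PedigreeOrderError(SirevalError, ValueError):
    """An operation requiring a validated, parent-first pedigree got a raw one."""


class ModelError(SirevalError, ValueError):
    """A trait model violates its invariants (non-PSD covariance, shape)."""


class LinkageError(SirevalError, KeyError):
    """A phenotype record refers to an animal absent from the pedigree."""


class IdentifiabilityError(SirevalError, ValueError):
    """The fixed-effect block is singular after the reference constraint."""


class EstimabilityError(SirevalError, ValueError):
    """A requested least-squares mean is not estimable (aliased levels)."""


class ConditioningError(SirevalError, ValueError):
    """A matrix that must be positive definite is singular or indefinite."""


class SchemaError(SirevalError, ValueError):
    """An input file does not match the expected column layout."""
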