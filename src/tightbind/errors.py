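"""Exception hierarchy shared across the package."""


class TightBindError(ValueError):
    """Base class for all domain errors raised by this package."""


class DomainError(TightBindError):
    """A parameter or argument is outside its physically meaningful domain."""


class DataError(TightBindError):
    """Input data violate a structural contract (shape, ordering, columns)."""


class FitError(TightBindError):
    """A fit cannot be attempted on the given input (distinct from a
    non-converged fit, which is returned as a flagged result)."""
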