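"""Package-wide exception and warning types."""


class ValidationError(ValueError):
    """A physical parameter, grid, or range violates its invariants."""


class UnsupportedModelError(ValidationError):
    """A solver was asked to handle a rheology family it does not support."""


class SchemaError(ValueError):
    """A motion-field container is missing a required dataset or attribute."""


class ObjectiveUndefinedError(RuntimeError):
    """Measured and simulated peaks share no valid abscissae."""


class ConditioningWarning(UserWarning):
    """A lossless configuration produced a (near-)singular spectral bin."""
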