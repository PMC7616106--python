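"""Exception types shared across the analysis modules."""


class ConfigurationError(ValueError):
    """A configuration field is missing, inconsistent or out of range."""


class ValidationError(ValueError):
    """Input data violate a schema or statistical precondition."""


class GenerationError(RuntimeError):
    """The synthetic-data generator produced an invalid intermediate value."""
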