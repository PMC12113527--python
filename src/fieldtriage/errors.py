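"""Exception types shared across the pipeline."""


class FieldTriageError(Exception):
    """Base class for package errors."""


class ValidationError(FieldTriageError):
    """A value or specification violates a documented invariant."""


class ConfigError(FieldTriageError):
    """A configuration references an unknown field, rule or option."""
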