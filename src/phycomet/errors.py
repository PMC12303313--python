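"""Typed exceptions raised by table readers and pipeline stages."""


class PhycometError(Exception):
    """Base class for all package errors."""


class SchemaError(PhycometError):
    """A required column or field is missing or malformed."""


class ValidationError(PhycometError):
    """Values violate a documented invariant (envelopes, enums, keys)."""


class DegenerateDataError(PhycometError):
    """The input carries no usable signal (all-zero, single class, ...)."""
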