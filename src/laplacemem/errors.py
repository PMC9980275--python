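"""Exception types shared across the package."""


class InvalidStateError(RuntimeError):
    """An operation was called on an object whose state cannot support it."""


class FormatError(ValueError):
    """A file did not conform to the documented on-disk format."""


class UndefinedCorrelationError(InvalidStateError):
    """A correlation was requested between histories with zero variance."""
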