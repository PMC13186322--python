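"""Exception types shared across the package."""


class OrthocellError(Exception):
    """Base class for package errors."""


class ConfigurationError(OrthocellError):
    """A user-supplied option or label does not match the data."""


class ValidationError(OrthocellError):
    """An input file or in-memory object violates a structural invariant."""
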