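"""Exception hierarchy shared across the package."""


class OrfrateError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(OrfrateError, ValueError):
    """Input violates a documented precondition (alphabet, length, range)."""


class ParseError(OrfrateError, ValueError):
    """A file could not be parsed; the message names the offending line/record."""


class SchemaError(OrfrateError, ValueError):
    """A tabular input lacks required columns."""


class ConfigurationError(OrfrateError, ValueError):
    """A requested computation is missing a required input or setting."""


class UnknownFeatureError(OrfrateError, KeyError):
    """A feature or term name was requested that the container does not hold."""
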