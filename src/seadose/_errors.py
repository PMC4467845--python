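"""Exception hierarchy.

All package-raised errors derive from :class:`SeadoseError` so callers can
catch one type at the pipeline boundary.
"""


class SeadoseError(Exception):
    """Base class for all errors raised by seadose."""


class ValidationError(SeadoseError):
    """A domain object or configuration value violates an invariant."""


class ConfigError(ValidationError):
    """A configuration file is malformed or contains an unknown/invalid key."""


class SchemaError(SeadoseError):
    """A tabular input does not match the expected column schema."""
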