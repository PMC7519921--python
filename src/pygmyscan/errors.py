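"""Exception hierarchy for pygmyscan."""


class PygmyscanError(Exception):
    """Base class for all pygmyscan errors."""


class ConfigurationError(PygmyscanError):
    """A configuration value is out of range, non-finite, or inconsistent."""


class ValidationError(PygmyscanError):
    """Input data violate a precondition (bad manifest, constant response, ...)."""


class ParseError(PygmyscanError):
    """A file could not be parsed."""
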