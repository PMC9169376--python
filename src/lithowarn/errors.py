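"""Exception hierarchy for lithowarn."""


class LithowarnError(Exception):
    """Base class for all lithowarn errors."""


class FormatError(LithowarnError):
    """A file does not conform to the expected recording schema."""


class ValidationError(LithowarnError):
    """Input data violates a documented invariant."""


class ConfigError(LithowarnError):
    """A configuration object is inconsistent or incomplete."""
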