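"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its documented contract."""


class InputFormatError(ValueError):
    """Raised when an input file or table is malformed; carries line context
    when available."""
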