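"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised for invalid configuration values (CLI exit code 2)."""


class DataError(ValueError):
    """Raised for malformed or inconsistent input data (CLI exit code 3)."""
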