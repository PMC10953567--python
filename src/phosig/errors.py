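"""Exception types shared across the package."""


class PhosigError(Exception):
    """Base class for all phosig errors."""


class ValidationError(PhosigError, ValueError):
    """An input file or in-memory table violates its contract."""


class ConfigurationError(PhosigError, ValueError):
    """A configuration value is out of range or inconsistent."""
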