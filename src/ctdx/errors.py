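"""Exception types shared across the package."""


class CtdxError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CtdxError, ValueError):
    """A configuration object is internally inconsistent or incomplete."""


class ValidationError(CtdxError, ValueError):
    """Input data violates a schema or a documented precondition."""
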