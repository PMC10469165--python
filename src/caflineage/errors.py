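class CaflineageError(Exception):
    """Base class for errors raised by this package."""


class ConfigError(CaflineageError):
    """Invalid configuration (bad proportions, inconsistent sizes, unknown keys)."""


class DataError(CaflineageError):
    """Input data violates a precondition (missing genes, empty groups, ...)."""
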