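"""Exception types shared across the pipeline."""


class MbnfError(Exception):
    """Base class for package errors."""


class ShapeMismatchError(MbnfError, ValueError):
    """Array dimensions do not agree with what the operation requires."""


class DegenerateDataError(MbnfError, ValueError):
    """Input has no usable variance (constant series, empty mask, ...)."""


class EngineStateError(MbnfError, RuntimeError):
    """Real-time engine method called out of order."""


class ConfigError(MbnfError, ValueError):
    """Configuration value out of range or unknown key."""
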