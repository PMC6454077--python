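"""Exception types shared across the package."""


class CtmpiError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CtmpiError, ValueError):
    """A caller-supplied value violates a precondition (bad grid, bad parameter)."""


class EstimationError(CtmpiError, RuntimeError):
    """An estimator cannot produce a value from the data it was given."""


class ConfigError(CtmpiError, ValueError):
    """A configuration file or dict is malformed; the message names the key."""
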