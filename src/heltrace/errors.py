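"""Exception hierarchy shared across the package."""


class HeltraceError(ValueError):
    """Base class for all errors raised by heltrace."""


class SpecError(HeltraceError):
    """A simulation spec violates one of its invariants."""


class AlphabetError(HeltraceError):
    """A sequence contains characters outside the expected alphabet."""


class SaturationError(HeltraceError):
    """A distance (or a distance-derived quantity) is beyond model saturation."""


class ConfigError(HeltraceError):
    """A configuration object (consensus, pipeline config, ...) is invalid."""
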