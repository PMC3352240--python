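"""Exception hierarchy for hebbsort."""


class HebbsortError(Exception):
    """Base class for all hebbsort errors."""


class InvalidConfigurationError(HebbsortError, ValueError):
    """A configuration value is outside its valid domain."""


class InvalidInputError(HebbsortError, ValueError):
    """An input array or argument violates a precondition."""


class DivergenceError(HebbsortError, ArithmeticError):
    """Hebbian learning produced non-finite weights (learning rate too large)."""


class StreamExhaustedError(HebbsortError, RuntimeError):
    """The spike stream ended before training completed."""


class UnsupportedParametersError(HebbsortError, ValueError):
    """Reference complexity constants are only published for the default parameters."""


class FormatError(HebbsortError, ValueError):
    """A file on disk does not conform to the expected format."""
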