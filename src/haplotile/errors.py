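"""Exception hierarchy shared across the pipeline."""


class HaplotileError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HaplotileError):
    """Invalid parameter combination (bad fractions, negative rates, ...)."""


class GenerationError(HaplotileError):
    """A simulation step could not honour its sequence budget."""


class InputError(HaplotileError):
    """Malformed or out-of-contract input data."""
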