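"""Exception hierarchy shared across the package."""


class PhasorNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PhasorNetError):
    """Invalid acquisition or experiment configuration."""


class InvalidParameterError(PhasorNetError):
    """Decay-model parameters outside their physical domain (or numerically degenerate)."""


class EmptyDecayError(PhasorNetError):
    """A decay histogram with zero total counts where photons are required."""


class DegenerateDecayError(PhasorNetError):
    """A decay whose shape defeats an estimator (e.g. zero counts in the peak channel)."""


class TrainingError(PhasorNetError):
    """Network training failed to produce a finite validated model."""


class FormatError(PhasorNetError):
    """A file on disk does not match the expected layout."""
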