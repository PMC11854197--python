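"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError / DataError and their
subclasses map to exit status 2 (usage or data problem), anything else
to 1 (internal error).
"""


class IgfuseError(Exception):
    """Base class for all package errors."""


class ConfigError(IgfuseError, ValueError):
    """Invalid configuration value (bad probability, unknown name, ...)."""


class DataError(IgfuseError, ValueError):
    """Malformed input data (labels outside {0,1}, NaN activations, ...)."""


class CapabilityError(IgfuseError, RuntimeError):
    """A pluggable backend (encoder, tagger) is not available.

    Raised instead of silently falling back to another backend.
    """


class DegenerateInputError(DataError):
    """Structurally valid input on which the operation is undefined
    (empty sequence, all positions masked, sequence shorter than kernel
    without padding)."""


class EstimationError(DataError):
    """Too little data to estimate a quantity (e.g. fusion weights from
    fewer samples than ``min_samples``)."""


class TrainingError(IgfuseError, RuntimeError):
    """Training cannot proceed (e.g. single-class corpus)."""


class MetricError(DataError):
    """A metric is undefined for the given inputs (e.g. AUC with a
    single class)."""
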