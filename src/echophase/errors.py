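"""Exception hierarchy shared across the package."""


class EchoPhaseError(Exception):
    """Base class for all echophase errors."""


class ConfigError(EchoPhaseError, ValueError):
    """A configuration object or parameter is invalid."""


class DomainError(EchoPhaseError, ValueError):
    """An argument is outside the operation's domain."""


class InfeasibleError(DomainError):
    """The request cannot be satisfied (e.g. too few frames to sample from)."""


class MissingMetadataError(EchoPhaseError, ValueError):
    """A frame record lacks required metadata (e.g. an LV tracing)."""


class DegenerateCropError(EchoPhaseError, ValueError):
    """A crop rectangle clipped to the image is empty."""


class DegenerateDataError(EchoPhaseError, ValueError):
    """A dataset is unusable for the requested operation (e.g. one class)."""


class UndefinedMetricError(EchoPhaseError, ValueError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""
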