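"""Exception hierarchy for the jet-monitoring pipeline."""


class JetVisionError(Exception):
    """Base class for all package errors."""


class FormatError(JetVisionError):
    """Input image has an unsupported layout (e.g. multi-channel colour)."""


class DimensionError(JetVisionError):
    """Array shapes violate a size contract (frame too small, template too big)."""


class ConfigError(JetVisionError):
    """Configuration file or parameter set is invalid."""


class ParameterError(JetVisionError):
    """Scene or operation parameters violate their invariants."""


class LocationError(JetVisionError):
    """Derived region of interest falls outside the usable frame area."""


class SequencingError(JetVisionError):
    """Frame verdicts arrived out of order."""


class AlignmentError(JetVisionError):
    """Prediction and ground-truth series cannot be aligned."""
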