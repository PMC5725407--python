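"""Exception hierarchy for the tritone pipeline."""


class TritoneError(Exception):
    """Base class for all tritone-specific errors."""


class ParseError(TritoneError):
    """A text input (voxel or boundary file) could not be parsed."""


class RangeError(TritoneError):
    """A voxel value lies outside the range allowed by the bit depth."""


class ConfigError(TritoneError):
    """A boundary configuration or run configuration is invalid."""


class ParameterError(TritoneError):
    """A scalar parameter is outside its valid domain."""


class SegmentationError(TritoneError):
    """Region polygons overlap after rasterization."""


class EmptyRegionError(TritoneError):
    """A region has no surviving (unmasked) pixels; its mean is undefined."""


class ReferenceError_(TritoneError):
    """The sensorimotor reference mean is non-positive."""


class FrequencyCollapseError(TritoneError):
    """The parietal detuning would drive its frequency to zero or below."""


class AliasingError(TritoneError):
    """An oscillator frequency is at or above the Nyquist limit."""
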