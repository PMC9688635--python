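"""Typed exceptions raised across the pipeline."""


class StainsightError(Exception):
    """Base class for all package errors."""


class PlacementError(StainsightError):
    """Objects could not be placed without overlap at the requested density."""


class FieldTooCrowdedError(StainsightError):
    """Too few candidate background pixels to estimate the background."""


class SampleSizeError(StainsightError):
    """Fewer objects than the analysis requires."""


class ConfigurationError(StainsightError):
    """Malformed or inconsistent configuration."""


class ImageFormatError(StainsightError):
    """Unsupported or unreadable image input."""
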