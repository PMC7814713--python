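"""Exception hierarchy shared across the pipeline."""


class SegpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SegpipeError):
    """A config value or registry lookup is invalid (unknown name, duplicate, bad key)."""


class ValidationError(SegpipeError):
    """Input data violates a documented precondition (shape, range, label set)."""


class FormatError(SegpipeError):
    """A file exists but does not parse as the expected format."""


class CoverageError(SegpipeError):
    """A patch grid left voxels of the source volume uncovered."""


class CacheError(SegpipeError):
    """A cached batch file is missing or unreadable."""


class ModelIOError(SegpipeError):
    """A model file could not be written or read back."""
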