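"""Exception hierarchy shared across the package."""


class DyadwarpError(Exception):
    """Base class for all package errors."""


class FormatError(DyadwarpError):
    """A file or record does not follow the documented dialect."""


class SegmentationError(DyadwarpError):
    """Task markers are inconsistent or a segment is unusable."""


class PreprocessError(DyadwarpError):
    """A screening step cannot produce a usable segment."""


class StatsError(DyadwarpError):
    """A statistical analysis received unusable input."""


class ConfigError(DyadwarpError):
    """A run configuration is invalid."""
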