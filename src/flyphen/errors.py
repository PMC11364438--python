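"""Exception hierarchy shared across the package."""


class FlyphenError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(FlyphenError, ValueError):
    """A caller-supplied argument violates a precondition."""


class InvalidInputError(FlyphenError, ValueError):
    """An input data structure violates its contract (shape, length, geometry)."""


class UndefinedStatisticError(FlyphenError, ValueError):
    """A requested statistic is undefined for the given data (e.g. empty group)."""


class LookupError_(FlyphenError, KeyError):
    """An unknown label was requested from a catalogue."""


class PlacementError(FlyphenError, RuntimeError):
    """Synthetic object placement failed after bounded retries."""


class SegmentationError(FlyphenError, RuntimeError):
    """Brain segmentation produced an empty or degenerate result."""
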