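"""Exception hierarchy.

Everything raised on bad user input derives from :class:`CatfusionError`
so callers (and the CLI) can catch one type.
"""


class CatfusionError(ValueError):
    """Base class for all validation failures in this package."""


class AlignmentError(CatfusionError):
    """Series that must share a clock have different lengths."""


class InsufficientDataError(CatfusionError):
    """Series too short for the requested lag embedding."""


class DegeneratePartitionError(CatfusionError):
    """Too few distinct values to build the requested partition."""


class ZeroEntropyError(CatfusionError):
    """A constant series carries no information to quantize or lag-select."""
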