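"""Exception hierarchy shared across the package."""


class MolarmarkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MolarmarkError):
    """A landmark/outline file could not be parsed; message names the location."""


class DimensionError(MolarmarkError):
    """Landmark count or matrix shape does not match expectations."""


class GeometryError(MolarmarkError):
    """Degenerate or invalid geometry (self-intersection, zero-size box, no ray crossing)."""


class UsageError(MolarmarkError):
    """The operation was called with arguments outside its contract."""


class CollinearityError(MolarmarkError):
    """A cross-product matrix is singular; message names the offending variables."""
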