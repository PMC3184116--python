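"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`InfarctSizeError`, so callers can catch one type at the batch level
and keep going with the next section.
"""


class InfarctSizeError(Exception):
    """Base class for all errors raised by infarctsize."""


class ValidationError(InfarctSizeError, ValueError):
    """An input violates a documented invariant (bad seed, bad polygon, ...)."""


class ImageFormatError(InfarctSizeError):
    """A section image file could not be decoded as 8-bit RGB."""


class SeedFileError(InfarctSizeError):
    """The seed/exclusion document is malformed (carries line/column when known)."""


class GeometryError(InfarctSizeError):
    """Midline geometry is undefined (no tissue, fewer than two valid rays, ...)."""


class UndefinedScoreError(InfarctSizeError):
    """A score has an empty denominator (no wall pixels / no midline length)."""
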