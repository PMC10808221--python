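"""Named exception hierarchy.

Validation problems (bad parameters, malformed configs) and I/O problems
are kept distinct so the command line can map them onto exit codes
2 and 3 respectively.
"""


class StedclustError(Exception):
    """Base class for all package errors."""


class ValidationError(StedclustError):
    """A parameter, configuration value or input contract was violated."""


class ShapeMismatchError(ValidationError):
    """Two images that must share a pixel grid do not."""


class BorderError(ValidationError):
    """A measurement footprint crosses the image border."""


class EmptyInputError(ValidationError):
    """An operation that needs at least one element received none."""


class InputOutputError(StedclustError):
    """A file could not be read or written."""


class UnsupportedImageError(InputOutputError):
    """The image file is not a single-page grayscale TIFF."""
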