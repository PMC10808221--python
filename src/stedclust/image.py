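"""Pixel images with a physical scale.

Every geometric parameter of the analysis (ROI diameters, linescan
lengths, distance thresholds) is specified in nanometres and converted
to pixels through :attr:`PixelImage.pixel_size_nm`. The coordinate
convention used throughout the package: pixel ``(row, col)`` covers the
square ``[col*p, (col+1)*p) x [row*p, (row+1)*p)`` in (x, y) nanometre
space, so its centre sits at ``((col+0.5)*p, (row+0.5)*p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError, ValidationError

DEFAULT_PIXEL_SIZE_NM = 20.0


@dataclass
class PixelImage:
    """A 2D non-negative intensity grid with a physical pixel size.

    Parameters
    ----------
    values
        2D array of intensities in arbitrary units; finite and >= 0.
    pixel_size_nm
        Edge length of one pixel in nanometres (default 20).
    channel
        Optional channel label (e.g. an antibody target) used to look up
        per-channel analysis parameters.
    """

    values: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    channel: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("image must be a non-empty 2D array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("image contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("image contains negative intensities")
        if not (np.isfinite(self.pixel_size_nm) and self.pixel_size_nm > 0):
            raise ValidationError("pixel_size_nm must be a positive finite length")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def area_um2(self) -> float:
        """Field area in square micrometres."""
        h, w = self.values.shape
        return h * w * (self.pixel_size_nm / 1000.0) ** 2

    def with_values(self, values: np.ndarray, channel: str | None = None) -> "PixelImage":
        """A new image on the same grid with replaced intensities."""
        return PixelImage(values, self.pixel_size_nm, channel or self.channel)

    def pixel_center_nm(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) nm coordinates of pixel centres."""
        p = self.pixel_size_nm
        return (np.asarray(col) + 0.5) * p, (np.asarray(row) + 0.5) * p


def check_same_grid(a: PixelImage, b: PixelImage) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"image shapes differ: {a.shape} vs {b.shape}")
    if not np.isclose(a.pixel_size_nm, b.pixel_size_nm):
        raise ShapeMismatchError("images have different pixel sizes")
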