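"""Reading images and writing result tables.

Physical scale comes from the analysis parameters (default 20 nm/px),
not from TIFF metadata, so the same parameter file governs every run.
CSV output uses a stable column order and locale-independent number
formatting; the run manifest records inputs, parameters and output
checksums so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputOutputError, UnsupportedImageError
from .image import PixelImage


def read_image(
    path: str | Path,
    pixel_size_nm: float = 20.0,
    channel: str | None = None,
) -> PixelImage:
    """Load a single-page grayscale TIFF (8/16-bit integer or 32-bit float)."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) != 1:
                raise UnsupportedImageError(
                    f"{path.name}: multi-page TIFFs are not supported"
                )
            data = tif.pages[0].asarray()
    except UnsupportedImageError:
        raise
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise InputOutputError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim != 2:
        raise UnsupportedImageError(
            f"{path.name}: expected a single-channel grayscale image, got shape {data.shape}"
        )
    if data.dtype.kind not in "uif":
        raise UnsupportedImageError(f"{path.name}: unsupported dtype {data.dtype}")
    return PixelImage(data.astype(np.float64), pixel_size_nm, channel)


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary sheet mask; any non-zero pixel counts as on-sheet."""
    img = read_image(path, pixel_size_nm=1.0)
    return img.values > 0


def write_csv(df: pd.DataFrame, path: str | Path) -> str:
    """Write a table with full-precision, locale-independent numbers."""
    path = Path(path)
    try:
        df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
    return sha256_file(path)


def write_json(obj, path: str | Path) -> str:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return sha256_file(path)


def sha256_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
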