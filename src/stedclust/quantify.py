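"""Per-maximum measurements and cluster classification.

Each detected maximum is measured on the preprocessed image:

* mean intensity in a 100 nm circular ROI (5 px diameter at 20 nm/px,
  a 13-pixel digital disk), background corrected, in both channels;
* the intensity-weighted centre of mass over the same ROI, giving
  sub-pixel positions in nm;
* a 31 px x 3 px linescan horizontally and vertically, each fitted with
  a Gaussian ``b + A*exp(-(x-mu)^2/(2*sigma^2))``; the better fit
  (higher R²) defines the spot, and its full width at half maximum
  ``2*sqrt(2*ln 2)*sigma`` the spot size.

A maximum is rated a *cluster* when the best fit has R² > 0.8 and its
peak lies within the central 10 pixels of the 31-sample profile
(|mu - 15| <= 5). Maxima too close to the border for the linescan
window are flagged and never rated as clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import FWHM_FACTOR, AnalysisParams
from .detect import MaximaList, border_flags
from .errors import BorderError, ValidationError
from .image import PixelImage

R2_SENTINEL = -np.inf


def disk_offsets(diameter_px: int) -> np.ndarray:
    """Integer (dr, dc) offsets of the digital disk of the given diameter.

    The diameter counts pixels across the centre row ("5 pixel
    diameter, the central pixel is the position"), so the Euclidean
    radius is ``(diameter - 1) / 2`` pixel centres: for diameter 5 the
    13-pixel disk (offsets with dr² + dc² <= 4).
    """
    if diameter_px <= 0 or diameter_px % 2 != 1:
        raise ValidationError("ROI diameter must be a positive odd pixel count")
    radius = (diameter_px - 1) / 2.0
    k = int(radius)
    offs = [
        (dr, dc)
        for dr in range(-k, k + 1)
        for dc in range(-k, k + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    return np.asarray(offs, dtype=np.int64)


def _roi_pixels(img: PixelImage, pos: tuple[int, int], diameter_px: int) -> tuple[np.ndarray, np.ndarray]:
    offs = disk_offsets(diameter_px)
    r = offs[:, 0] + pos[0]
    c = offs[:, 1] + pos[1]
    h, w = img.shape
    if r.min() < 0 or c.min() < 0 or r.max() >= h or c.max() >= w:
        raise BorderError(f"ROI footprint at {pos} crosses the image border")
    return r, c


def roi_mean(img: PixelImage, pos: tuple[int, int], diameter_px: int = 5) -> float:
    """Mean intensity over the digital disk centred on ``pos``."""
    r, c = _roi_pixels(img, pos, diameter_px)
    return float(img.values[r, c].mean())


def background_correct(raw: float, bg: float) -> float:
    """Subtract the off-sheet background; negative results are retained."""
    return raw - bg


def mass_center(
    img: PixelImage,
    pos: tuple[int, int],
    diameter_px: int = 5,
    background: float = 0.0,
) -> tuple[float, float]:
    """Sub-pixel (x, y) position in nm: intensity-weighted ROI centroid.

    Weights are background-corrected intensities clipped at zero, so
    off-sheet noise cannot drag the centroid. Zero total weight falls
    back to the central pixel centre.
    """
    r, c = _roi_pixels(img, pos, diameter_px)
    w = np.clip(img.values[r, c] - background, 0.0, None)
    total = w.sum()
    p = img.pixel_size_nm
    if total <= 0:
        return (pos[1] + 0.5) * p, (pos[0] + 0.5) * p
    x = float(((c + 0.5) * w).sum() / total) * p
    y = float(((r + 0.5) * w).sum() / total) * p
    return x, y


def linescan_profiles(
    img: PixelImage,
    pos: tuple[int, int],
    length_px: int = 31,
    width_px: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal and vertical linescan profiles through a maximum.

    Each profile is the across-width mean of ``width_px`` rows
    (columns) centred on ``pos``, sampled at ``length_px`` positions
    along the scan. Raises :class:`BorderError` when the window does
    not fit; callers flag such maxima instead of fitting them.
    """
    half, wh = length_px // 2, width_px // 2
    r, c = pos
    h, w = img.shape
    if r - wh < 0 or r + wh >= h or c - half < 0 or c + half >= w or r - half < 0 or r + half >= h or c - wh < 0 or c + wh >= w:
        raise BorderError(f"linescan window at {pos} crosses the image border")
    horizontal = img.values[r - wh:r + wh + 1, c - half:c + half + 1].mean(axis=0)
    vertical = img.values[r - half:r + half + 1, c - wh:c + wh + 1].mean(axis=1)
    return horizontal, vertical


@dataclass
class LinescanFit:
    """Gaussian fit of one intensity profile."""

    orientation: str  # "horizontal" | "vertical"
    A: float = np.nan
    mu: float = np.nan
    sigma: float = np.nan
    b: float = np.nan
    r2: float = R2_SENTINEL

    @property
    def converged(self) -> bool:
        return np.isfinite(self.r2)


def _gauss(x: np.ndarray, A: float, mu: float, sigma: float, b: float) -> np.ndarray:
    return b + A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_profile(profile: np.ndarray, orientation: str = "horizontal") -> LinescanFit:
    """Least-squares Gaussian fit with an additive offset.

    Constraints: A >= 0, mu in [0, n-1], sigma in [0.5, 15] px. A flat
    (zero-variance) profile or a non-converging fit returns the R²
    sentinel (-inf) so it can never pass the cluster criterion.
    """
    y = np.asarray(profile, dtype=np.float64)
    if y.ndim != 1 or not np.all(np.isfinite(y)):
        raise ValidationError("profile must be a finite 1D array")
    n = len(y)
    x = np.arange(n, dtype=np.float64)
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot <= 0:
        return LinescanFit(orientation)

    lo = (0.0, 0.0, 0.5, -np.inf)
    hi = (np.inf, float(n - 1), 15.0, np.inf)
    b0 = float(y.min())
    A0 = max(float(y.max() - y.min()), 1e-12)
    mu0 = float(np.argmax(y))
    best: tuple[float, np.ndarray] | None = None
    # one start suffices for well-formed peaks; fall back to wider/narrower
    # width guesses only when the first fit is absent or visibly poor
    for sigma0 in (2.0, 1.0, 4.0):
        try:
            popt, _ = curve_fit(
                _gauss, x, y, p0=(A0, mu0, sigma0, b0), bounds=(lo, hi), maxfev=1000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(((y - _gauss(x, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
        if best[0] < 0.05 * sstot:
            break
    if best is None:
        return LinescanFit(orientation)
    sse, popt = best
    r2 = 1.0 - sse / sstot
    return LinescanFit(orientation, float(popt[0]), float(popt[1]), float(popt[2]), float(popt[3]), r2)


def fwhm_nm(fit: LinescanFit, pixel_size_nm: float) -> float:
    """Full width at half maximum of a fitted profile, in nm."""
    return FWHM_FACTOR * fit.sigma * pixel_size_nm


def classify_cluster(
    best: LinescanFit,
    border_flag: bool,
    r2_threshold: float = 0.8,
    center_index: int = 15,
    center_window_px: float = 5.0,
) -> bool:
    """Cluster criterion: best R² strictly above threshold and centred peak."""
    if border_flag or not best.converged:
        return False
    return bool(best.r2 > r2_threshold and abs(best.mu - center_index) <= center_window_px)


def measure_maxima(
    img_self: PixelImage,
    img_other: PixelImage,
    maxima: MaximaList,
    params: AnalysisParams,
    background_self: float = 0.0,
    background_other: float = 0.0,
) -> pd.DataFrame:
    """Measure and classify every maximum of one channel.

    Returns one row per maximum: pixel position, sub-pixel mass centre
    (nm), background-corrected ROI intensities in both channels, the
    best linescan fit, FWHM, and the cluster decision. Intensities of
    border-flagged maxima are still measured when the (smaller) ROI
    footprint fits; their fits are left NaN and they are never clusters.
    """
    rows = []
    flags = border_flags(maxima.positions, img_self.shape, params.linescan_half_px)
    for (r, c), border in zip(maxima.positions, flags):
        pos = (int(r), int(c))
        try:
            raw_self = roi_mean(img_self, pos, params.roi_diameter_px)
            raw_other = roi_mean(img_other, pos, params.roi_diameter_px)
            i_self = background_correct(raw_self, background_self)
            i_other = background_correct(raw_other, background_other)
            x_nm, y_nm = mass_center(img_self, pos, params.roi_diameter_px, background_self)
        except BorderError:
            i_self = i_other = x_nm = y_nm = np.nan
        if border:
            best = LinescanFit("horizontal")
        else:
            hor, ver = linescan_profiles(
                img_self, pos, params.linescan_length_px, params.linescan_width_px
            )
            fit_h = fit_gaussian_profile(hor, "horizontal")
            fit_v = fit_gaussian_profile(ver, "vertical")
            # strictly higher R² wins; an exact tie goes to the horizontal scan
            best = fit_v if fit_v.r2 > fit_h.r2 else fit_h
        is_cluster = classify_cluster(
            best, bool(border), params.r2_threshold, params.center_index, params.center_window_px
        )
        rows.append(
            {
                "row": pos[0],
                "col": pos[1],
                "x_nm": x_nm,
                "y_nm": y_nm,
                "intensity_self": i_self,
                "intensity_other": i_other,
                "A": best.A,
                "mu_px": best.mu,
                "sigma_px": best.sigma,
                "offset": best.b,
                "r2": best.r2 if best.converged else np.nan,
                "orientation": best.orientation if best.converged else "",
                "fwhm_nm": fwhm_nm(best, img_self.pixel_size_nm) if best.converged else np.nan,
                "is_cluster": is_cluster,
                "border_flag": bool(border),
            }
        )
    columns = [
        "row", "col", "x_nm", "y_nm", "intensity_self", "intensity_other",
        "A", "mu_px", "sigma_px", "offset", "r2", "orientation", "fwhm_nm",
        "is_cluster", "border_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
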