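"""Preprocessing and prominence-based local-maxima detection.

The maxima finder reproduces the behaviour of an ImageJ-style
"find maxima with noise tolerance" operation, defined here by an
explicit flood-fill contract:

A candidate pixel ``p`` (greater than or equal to all of its
8-neighbours; outside-image neighbours count as minus infinity) is
reported as a maximum iff the 8-connected region of pixels with value
``> I(p) - tolerance`` reachable from ``p`` contains neither a pixel
higher than ``I(p)`` nor an already-accepted maximum. Candidates are
processed in descending intensity order (ties row-major), so of two
peaks joined by a shallow saddle only the higher survives. An
equal-valued plateau of candidates yields exactly one maximum: the
plateau pixel nearest the plateau centroid, ties broken row-major.
A plateau with no strictly lower in-image neighbour (e.g. a constant
image) has no prominence and yields nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import ShapeMismatchError, ValidationError
from .image import PixelImage, check_same_grid

_NEIGHBORS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class MaximaList:
    """Detected maxima of one channel image.

    positions is an ``(n, 2)`` integer array of (row, col) pixel
    coordinates, unique and inside the image.
    """

    positions: np.ndarray
    noise_tolerance: float
    source_channel: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.positions)

    def positions_nm(self, pixel_size_nm: float) -> np.ndarray:
        """(x, y) nm coordinates of the maxima pixel centres, shape (n, 2)."""
        xy = np.empty((len(self.positions), 2))
        xy[:, 0] = (self.positions[:, 1] + 0.5) * pixel_size_nm
        xy[:, 1] = (self.positions[:, 0] + 0.5) * pixel_size_nm
        return xy


def correct_crosstalk(long_red: PixelImage, red: PixelImage, factor: float = 0.5) -> PixelImage:
    """Subtract a fixed fraction of one spectral channel from another.

    Removes co-excitation bleed-through: ``out = max(long_red - factor*red, 0)``.
    """
    check_same_grid(long_red, red)
    if not 0.0 <= factor <= 1.0:
        raise ValidationError("crosstalk factor must lie in [0, 1]")
    corrected = np.clip(long_red.values - factor * red.values, 0.0, None)
    return long_red.with_values(corrected)


def gaussian_blur(img: PixelImage, sigma_px: float = 0.5) -> PixelImage:
    """Gaussian noise reduction (reflective boundary); sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValidationError("blur sigma must be >= 0")
    if sigma_px == 0:
        return img.with_values(img.values.copy())
    return img.with_values(ndimage.gaussian_filter(img.values, sigma_px, mode="reflect"))


def _candidate_plateaus(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate plateau representatives and their intensities.

    Returns (reps, vals): reps is (k, 2) int array of (row, col), one per
    plateau, vals the plateau intensity. Candidates are pixels >= all
    8-neighbours; 8-adjacent candidates necessarily share one value, so
    connected components of the candidate mask are the plateaus.
    """
    h, w = values.shape
    cand = np.ones((h, w), dtype=bool)
    for dr, dc in _NEIGHBORS:
        shifted = np.full((h, w), -np.inf)
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        shifted[r0:r1, c0:c1] = values[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        cand &= values >= shifted
    labels, nlab = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    if nlab == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty(0)

    # a plateau must have at least one strictly lower in-image neighbour,
    # otherwise it has no prominence (constant image)
    lower_any = np.zeros((h, w), dtype=bool)
    for dr, dc in _NEIGHBORS:
        shifted = np.full((h, w), np.inf)
        r0, r1 = max(dr, 0), h + min(dr, 0)
        c0, c1 = max(dc, 0), w + min(dc, 0)
        shifted[r0:r1, c0:c1] = values[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        lower_any |= shifted < values

    rows, cols = np.nonzero(cand)
    labs = labels[rows, cols]
    counts = np.bincount(labs, minlength=nlab + 1)
    cen_r = np.bincount(labs, weights=rows, minlength=nlab + 1) / np.maximum(counts, 1)
    cen_c = np.bincount(labs, weights=cols, minlength=nlab + 1) / np.maximum(counts, 1)
    d2 = (rows - cen_r[labs]) ** 2 + (cols - cen_c[labs]) ** 2
    # per plateau: member nearest the centroid, ties row-major
    order = np.lexsort((cols, rows, d2, labs))
    first = np.ones(len(order), dtype=bool)
    first[1:] = labs[order][1:] != labs[order][:-1]
    rep_idx = order[first]
    haslow = (
        np.bincount(labs, weights=lower_any[rows, cols].astype(float), minlength=nlab + 1) > 0
    )
    keep = haslow[labs[rep_idx]]
    reps = np.stack([rows[rep_idx], cols[rep_idx]], axis=1)[keep]
    vals = values[reps[:, 0], reps[:, 1]] if len(reps) else np.empty(0)
    return reps.astype(np.int64), np.asarray(vals, dtype=np.float64)


@njit(cache=True)
def _flood_accept(values, order, reps_r, reps_c, vals, tol):  # pragma: no cover
    """Flood-fill acceptance loop of the maxima contract (compiled).

    For each plateau representative, in the given (descending-value)
    order, breadth-first flood the 8-connected region with value
    > v0 - tol; reject on reaching a higher pixel or an accepted
    maximum, accept otherwise. Returns a 0/1 flag per representative.
    """
    h, w = values.shape
    n = len(order)
    visited = np.zeros((h, w), dtype=np.int32)
    accepted_mask = np.zeros((h, w), dtype=np.uint8)
    out = np.zeros(n, dtype=np.uint8)
    qr = np.empty(h * w, dtype=np.int32)
    qc = np.empty(h * w, dtype=np.int32)
    stamp = 0
    for oi in range(n):
        idx = order[oi]
        r0 = reps_r[idx]
        c0 = reps_c[idx]
        v0 = vals[idx]
        thr = v0 - tol
        stamp += 1
        head = 0
        tail = 0
        qr[tail] = r0
        qc[tail] = c0
        tail += 1
        visited[r0, c0] = stamp
        ok = True
        while head < tail:
            r = qr[head]
            c = qc[head]
            head += 1
            if values[r, c] > v0 or accepted_mask[r, c] == 1:
                ok = False
                break
            for dr in range(-1, 2):
                for dc in range(-1, 2):
                    if dr == 0 and dc == 0:
                        continue
                    rr = r + dr
                    cc = c + dc
                    if (
                        0 <= rr < h
                        and 0 <= cc < w
                        and visited[rr, cc] != stamp
                        and values[rr, cc] > thr
                    ):
                        visited[rr, cc] = stamp
                        qr[tail] = rr
                        qc[tail] = cc
                        tail += 1
        if ok:
            out[idx] = 1
            accepted_mask[r0, c0] = 1
    return out


def find_maxima(
    img: PixelImage,
    noise_tolerance: float,
    exclude_edge_maxima: bool = False,
) -> MaximaList:
    """Detect local maxima with a noise-tolerance (prominence) criterion.

    See the module docstring for the normative flood-fill contract.
    ``exclude_edge_maxima`` drops accepted maxima lying on the outermost
    pixel row or column (off by default).
    """
    if not (np.isfinite(noise_tolerance) and noise_tolerance > 0):
        raise ValidationError("noise_tolerance must be > 0")
    values = img.values
    h, w = values.shape
    reps, vals = _candidate_plateaus(values)
    if len(reps) == 0:
        return MaximaList(np.empty((0, 2)), noise_tolerance, img.channel)

    # descending value, ties row-major
    order = np.lexsort((reps[:, 1], reps[:, 0], -vals))
    accepted = _flood_accept(
        np.ascontiguousarray(values),
        order.astype(np.int64),
        reps[:, 0].astype(np.int64),
        reps[:, 1].astype(np.int64),
        vals.astype(np.float64),
        float(noise_tolerance),
    )
    pos = reps[accepted.astype(bool)]
    if exclude_edge_maxima and len(pos):
        keep = (pos[:, 0] > 0) & (pos[:, 0] < h - 1) & (pos[:, 1] > 0) & (pos[:, 1] < w - 1)
        pos = pos[keep]
    return MaximaList(pos, noise_tolerance, img.channel)


def border_flags(positions: np.ndarray, shape: tuple[int, int], margin_px: int = 15) -> np.ndarray:
    """True for maxima closer than ``margin_px`` to any image border.

    Such maxima cannot host the full linescan window; downstream
    classification marks them and never rates them as clusters.
    """
    positions = np.asarray(positions, dtype=np.int64).reshape(-1, 2)
    h, w = shape
    r, c = positions[:, 0], positions[:, 1]
    return (r < margin_px) | (c < margin_px) | (r >= h - margin_px) | (c >= w - margin_px)
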