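"""Spatial statistics on detected objects.

Two families of measurements:

* **Object-based colocalization** — for every cluster of a source
  channel, the Euclidean distance to the nearest cluster of the target
  channel (sub-pixel mass-centre positions, nm). Clusters closer than
  60 nm centre-to-centre are counted as overlapping; the analysis is
  directional (A→B need not equal B→A) and both directions are
  reported.

* **Crowding** — for every maximum (pixel positions, all maxima, not
  only clusters) the number of other same-channel maxima within a
  900 nm diameter circle; the centre is never its own neighbour. Under
  complete spatial randomness at intensity λ the counts average
  λ·π·(0.45 µm)² and the percentage histogram is close to normal;
  agglomeration into arranged crowds adds a second, higher-mean
  component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError, ValidationError

DEFAULT_OVERLAP_THRESHOLD_NM = 60.0
DEFAULT_NEIGHBOR_DIAMETER_NM = 900.0


@dataclass
class DistanceResult:
    """Per-source-cluster shortest distance to the target channel."""

    distances_nm: np.ndarray
    threshold_nm: float = DEFAULT_OVERLAP_THRESHOLD_NM

    def __post_init__(self) -> None:
        self.distances_nm = np.asarray(self.distances_nm, dtype=np.float64).ravel()

    @property
    def overlap_flags(self) -> np.ndarray:
        return self.distances_nm <= self.threshold_nm

    def __len__(self) -> int:
        return len(self.distances_nm)


@dataclass
class NeighborCounts:
    """Per-maximum count of same-channel maxima within the search circle."""

    counts: np.ndarray
    circle_diameter_nm: float = DEFAULT_NEIGHBOR_DIAMETER_NM

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64).ravel()

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class PercentHistogram:
    """Histogram expressed as percentages of n observations."""

    bin_centers: np.ndarray
    percentages: np.ndarray
    n: int
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.percentages = np.asarray(self.percentages, dtype=np.float64)
        if self.n <= 0:
            raise ValidationError("histogram requires n > 0 observations")


def _as_xy(points: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise EmptyInputError(f"{name} positions are empty")
    pts = pts.reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise ValidationError(f"{name} positions contain non-finite values")
    return pts


def shortest_cross_distances(
    src_nm: np.ndarray,
    dst_nm: np.ndarray,
    threshold_nm: float = DEFAULT_OVERLAP_THRESHOLD_NM,
) -> DistanceResult:
    """Nearest-neighbour distance from every source cluster to the target set.

    Directional: called once per channel ordering. ``src`` and ``dst``
    are (n, 2) arrays of (x, y) positions in nm (mass centres).
    """
    src = _as_xy(src_nm, "source")
    dst = _as_xy(dst_nm, "target")
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return DistanceResult(d, threshold_nm)


def overlap_fraction(result: DistanceResult) -> float:
    """Fraction of source clusters within the overlap threshold (inclusive)."""
    if len(result) == 0:
        raise EmptyInputError("no distances to summarize")
    return float(result.overlap_flags.mean())


def distance_histogram(result: DistanceResult, bin_nm: float = 10.0) -> PercentHistogram:
    """Percentage of source clusters per distance bin ([0,bin), [bin,2bin), ...)."""
    if bin_nm <= 0:
        raise ValidationError("bin width must be > 0")
    d = result.distances_nm
    if len(d) == 0:
        raise EmptyInputError("no distances to histogram")
    nbins = int(np.floor(d.max() / bin_nm)) + 1
    edges = np.arange(nbins + 1) * bin_nm
    counts, _ = np.histogram(d, bins=edges)
    return PercentHistogram(
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        percentages=100.0 * counts / len(d),
        n=len(d),
        bin_width=bin_nm,
    )


def neighbor_counts(
    positions_nm: np.ndarray,
    diameter_nm: float = DEFAULT_NEIGHBOR_DIAMETER_NM,
) -> NeighborCounts:
    """Same-channel crowding: neighbours within ``diameter/2`` (inclusive).

    One is subtracted from each in-circle count so a maximum is not its
    own neighbour.
    """
    if diameter_nm <= 0:
        raise ValidationError("circle diameter must be > 0")
    pts = np.asarray(positions_nm, dtype=np.float64).reshape(-1, 2)
    if len(pts) == 0:
        return NeighborCounts(np.empty(0, dtype=np.int64), diameter_nm)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=diameter_nm / 2.0, return_length=True) - 1
    return NeighborCounts(counts, diameter_nm)


def count_histogram(counts: NeighborCounts) -> PercentHistogram:
    """Percentage of maxima per integer neighbour count (unit bins)."""
    c = counts.counts
    if len(c) == 0:
        raise EmptyInputError("no counts to histogram")
    values = np.arange(int(c.max()) + 1)
    occ = np.bincount(c, minlength=len(values))
    return PercentHistogram(
        bin_centers=values.astype(float),
        percentages=100.0 * occ / len(c),
        n=len(c),
        bin_width=1.0,
    )


def interior_mask(
    positions_nm: np.ndarray,
    field_size_nm: tuple[float, float],
    margin_nm: float,
) -> np.ndarray:
    """True for points farther than ``margin_nm`` from every field edge.

    Edge correction for analytic comparisons: a search circle centred on
    an interior point lies fully inside the field, so its count is an
    unbiased estimate of λ times the circle area.
    """
    pts = np.asarray(positions_nm, dtype=np.float64).reshape(-1, 2)
    w, h = field_size_nm
    return (
        (pts[:, 0] >= margin_nm)
        & (pts[:, 0] <= w - margin_nm)
        & (pts[:, 1] >= margin_nm)
        & (pts[:, 1] <= h - margin_nm)
    )


def cluster_density(n_clusters: int, area_um2: float) -> float:
    """Clusters per µm² of analysed sheet area."""
    if area_um2 <= 0:
        raise ValidationError("sheet area must be > 0")
    if n_clusters < 0:
        raise ValidationError("cluster count must be >= 0")
    return n_clusters / area_um2
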