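"""Independent reference implementations used as oracles.

These deliberately avoid the package's algorithms: the maxima oracle
resolves flood reachability through connected-component labelling of a
thresholded mask (instead of breadth-first search), and the spatial
oracles enumerate all pairs.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_N8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def ref_find_maxima(values: np.ndarray, tol: float) -> set[tuple[int, int]]:
    """Reference maxima finder following the flood-fill contract literally."""
    values = np.asarray(values, dtype=np.float64)
    h, w = values.shape

    def neighbors(r, c):
        for dr, dc in _N8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    # candidate pixels: >= all 8-neighbours (outside-image = -inf)
    cand = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            v = values[r, c]
            cand[r, c] = all(values[rr, cc] <= v for rr, cc in neighbors(r, c))

    # plateaus: connected equal-valued candidate groups
    seen = np.zeros((h, w), dtype=bool)
    reps: list[tuple[float, int, int]] = []
    for r in range(h):
        for c in range(w):
            if not cand[r, c] or seen[r, c]:
                continue
            v = values[r, c]
            member = [(r, c)]
            seen[r, c] = True
            stack = [(r, c)]
            while stack:
                pr, pc = stack.pop()
                for rr, cc in neighbors(pr, pc):
                    if cand[rr, cc] and not seen[rr, cc] and values[rr, cc] == v:
                        seen[rr, cc] = True
                        member.append((rr, cc))
                        stack.append((rr, cc))
            # plateau must border at least one strictly lower in-image pixel
            if not any(
                values[rr, cc] < v for mr, mc in member for rr, cc in neighbors(mr, mc)
            ):
                continue
            cr = sum(m[0] for m in member) / len(member)
            cc_ = sum(m[1] for m in member) / len(member)
            rep = min(member, key=lambda m: ((m[0] - cr) ** 2 + (m[1] - cc_) ** 2, m[0], m[1]))
            reps.append((v, rep[0], rep[1]))

    # process in descending value, ties row-major
    reps.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[int, int]] = []
    structure = np.ones((3, 3), dtype=int)
    for v0, r0, c0 in reps:
        mask = values > v0 - tol
        labels, _ = ndimage.label(mask, structure=structure)
        region = labels == labels[r0, c0]
        if values[region].max() > v0:
            continue
        if any(region[ar, ac] for ar, ac in accepted):
            continue
        accepted.append((r0, c0))
    return set(accepted)


def ref_nearest_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """All-pairs nearest-neighbour distances from src to dst."""
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    out = np.empty(len(src))
    for i, p in enumerate(src):
        out[i] = np.sqrt(((dst - p) ** 2).sum(axis=1)).min()
    return out


def ref_neighbor_counts(points: np.ndarray, diameter: float) -> np.ndarray:
    """All-pairs in-circle counts (radius inclusive), self excluded."""
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    out = np.zeros(n, dtype=np.int64)
    r = diameter / 2.0
    for i in range(n):
        d = np.sqrt(((points - points[i]) ** 2).sum(axis=1))
        out[i] = int((d <= r).sum()) - 1
    return out


def ref_dense_gaussian_convolution(values: np.ndarray, sigma: float) -> np.ndarray:
    """Direct dense convolution with a truncated, normalized Gaussian kernel.

    Kernel radius 4*sigma (rounded), reflective boundary, separable
    passes done as explicit dense sums.
    """
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()

    def conv1d(arr: np.ndarray) -> np.ndarray:
        n = len(arr)
        padded = np.concatenate([arr[radius:0:-1], arr, arr[-2:-radius - 2:-1]])
        return np.array(
            [float((padded[i:i + 2 * radius + 1] * kernel).sum()) for i in range(n)]
        )

    rows = np.apply_along_axis(conv1d, 1, values)
    return np.apply_along_axis(conv1d, 0, rows)
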