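"""Statistical models of the crowding and intensity analyses.

* :func:`fit_crowding_mixture` decomposes a neighboured-maxima
  percentage histogram into one or two Gaussian components by nonlinear
  least squares. The area fraction of component i is
  ``A_i * sigma_i / sum_j A_j * sigma_j`` (the area under an
  unnormalized Gaussian is proportional to amplitude times width); the
  higher-mean component quantifies the arranged-crowd population. An
  F-test on the residual-sum-of-squares reduction (3 extra parameters)
  decides whether the two-component model is preferred.

* :func:`origin_regression` is the closed-form regression through the
  origin, ``slope = Σxy / Σx²``, with R² defined about the mean of y —
  which can be negative when the data segregate into populations that a
  proportional model cannot describe. Points are also split by the
  2 a.u. noise gate into both-channel, self-only and below-noise
  fractions.

* :func:`aggregate_replicates` averages per-sheet metrics within
  biological replicates and compares two conditions with a two-sided,
  unpaired (equal-variance) Student's t-test on the replicate means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .errors import EmptyInputError, ValidationError
from .spatial import PercentHistogram

DEFAULT_NOISE_LEVEL_AU = 2.0


@dataclass
class GaussianComponent:
    amplitude: float
    mean: float
    sd: float


@dataclass
class MixtureFit:
    """One- or two-Gaussian decomposition of a percentage histogram."""

    components: list[GaussianComponent]
    area_fractions: np.ndarray
    r2: float
    sse: float
    model_preferred: str  # "single" | "double"
    f_pvalue: float = np.nan

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        y = np.zeros_like(x)
        for comp in self.components:
            y += comp.amplitude * np.exp(-((x - comp.mean) ** 2) / (2 * comp.sd**2))
        return y


def _sum_of_gaussians(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for a, m, s in zip(params[0::3], params[1::3], params[2::3]):
        y = y + a * np.exp(-((x - m) ** 2) / (2 * s**2))
    return y


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    return float(np.interp(q, cw, x[order]))


def _fit_k(
    x: np.ndarray, y: np.ndarray, k: int, bin_width: float, starts=None
) -> tuple[np.ndarray, float]:
    """Best-of-multi-start least squares for a k-component model."""
    span = float(x.max() - x.min()) if len(x) > 1 else 1.0
    amax = max(float(y.max()), 1e-9)
    sigma_lo = 0.5 * bin_width
    lo = [0.0, float(x.min()) - 2 * bin_width, sigma_lo] * k
    hi = [np.inf, float(x.max()) + 2 * bin_width, max(span, 2 * sigma_lo)] * k
    w = np.clip(y, 0, None)
    if w.sum() <= 0:
        raise ValidationError("histogram has no mass to fit")
    if starts is None:
        if k == 1:
            mu0 = _weighted_quantile(x, w, 0.5)
            starts = [[(amax, mu0, max(span / 6, sigma_lo))]]
        else:
            # quantile-based means, several width/quantile combinations
            qpairs = [(0.25, 0.75), (0.10, 0.90), (0.35, 0.65), (0.5, 0.9)]
            widths = [max(span / 8, sigma_lo), max(span / 4, sigma_lo)]
            starts = [
                [(amax, _weighted_quantile(x, w, qa), s1),
                 (amax / 3, _weighted_quantile(x, w, qb), s2)]
                for (qa, qb) in qpairs
                for s1, s2 in itertools.product(widths, widths)
            ]
    best: tuple[float, np.ndarray] | None = None
    for start in starts:
        p0 = np.asarray([v for comp in start for v in comp], dtype=np.float64)
        p0 = np.clip(p0, lo, hi)
        try:
            popt, _ = curve_fit(
                _sum_of_gaussians, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(((y - _sum_of_gaussians(x, *popt)) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, popt)
    if best is None:
        raise ValidationError("mixture fit did not converge from any start")
    return best[1], best[0]


def fit_crowding_mixture(
    hist: PercentHistogram, k: int = 2, starts=None
) -> MixtureFit:
    """Decompose a crowding percentage histogram into k Gaussians.

    ``starts`` optionally overrides the deterministic multi-start list
    (each start: list of k (amplitude, mean, sd) triples); the returned
    solution is start-order invariant because the lowest-SSE fit wins.
    For k=2 at least 6 non-empty bins are required (6 free parameters).
    """
    if k not in (1, 2):
        raise ValidationError("k must be 1 or 2")
    x = hist.bin_centers
    y = hist.percentages
    nonempty = int(np.count_nonzero(y > 0))
    if k == 2 and nonempty < 6:
        raise ValidationError(
            f"two-component fit needs >= 6 non-empty bins, got {nonempty}"
        )
    popt, sse = _fit_k(x, y, k, hist.bin_width, starts=starts)
    comps = [
        GaussianComponent(float(a), float(m), float(s))
        for a, m, s in zip(popt[0::3], popt[1::3], popt[2::3])
    ]
    comps.sort(key=lambda c: c.mean)
    areas = np.array([c.amplitude * c.sd for c in comps])
    total = areas.sum()
    fractions = areas / total if total > 0 else np.full(k, 1.0 / k)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sstot if sstot > 0 else np.nan

    # model preference: F-test on the SSE reduction of double over single
    preferred, f_p = "single", np.nan
    if nonempty >= 6:
        if k == 2:
            _, sse1 = _fit_k(x, y, 1, hist.bin_width)
            sse2 = sse
        else:
            sse1 = sse
            _, sse2 = _fit_k(x, y, 2, hist.bin_width)
        df2 = len(x) - 6
        # a numerically perfect single fit cannot be improved upon
        if sse1 <= 1e-9 * max(sstot, 1.0):
            df2 = 0
        if df2 > 0 and sse2 > 0:
            fstat = ((sse1 - sse2) / 3.0) / (sse2 / df2)
            f_p = float(sps.f.sf(max(fstat, 0.0), 3, df2))
            if f_p < 0.05:
                preferred = "double"
    return MixtureFit(comps, fractions, r2, sse, preferred, f_p)


@dataclass
class OriginRegression:
    """Through-origin linear regression with noise-gate fractions."""

    slope: float
    r2: float
    n: int
    frac_both: float
    frac_self_only: float
    frac_below_noise: float
    noise_level_au: float = DEFAULT_NOISE_LEVEL_AU


def origin_regression(
    x: np.ndarray, y: np.ndarray, noise_level_au: float = DEFAULT_NOISE_LEVEL_AU
) -> OriginRegression:
    """Closed-form regression of y on x through the origin.

    ``slope = Σxy/Σx²``; ``R² = 1 − Σ(y − slope·x)²/Σ(y − ȳ)²`` (about
    the mean, may be negative). Intensities at or below the noise level
    gate the points: x above and y above → both channels; x above, y at
    or below → self only; x at or below → below noise.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 2:
        raise EmptyInputError("regression needs at least 2 paired intensities")
    sxx = float((x * x).sum())
    if sxx == 0:
        slope, r2 = 0.0, np.nan
    else:
        slope = float((x * y).sum() / sxx)
        sstot = float(((y - y.mean()) ** 2).sum())
        ssres = float(((y - slope * x) ** 2).sum())
        r2 = 1.0 - ssres / sstot if sstot > 0 else np.nan
    t = noise_level_au
    below = x <= t
    both = (~below) & (y > t)
    self_only = (~below) & (y <= t)
    n = len(x)
    return OriginRegression(
        slope, r2, n,
        float(both.mean()), float(self_only.mean()), float(below.mean()), t,
    )


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ReplicateSummary:
    """Replicate-level aggregate of one metric for two conditions."""

    condition_a: str
    condition_b: str
    means_a: np.ndarray
    means_b: np.ndarray
    grand_mean_a: float
    grand_mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    stars: str


def aggregate_replicates(
    data: pd.DataFrame,
    value: str = "value",
    condition: str = "condition",
    replicate: str = "replicate",
    welch: bool = False,
) -> ReplicateSummary:
    """Mean per replicate, grand mean ± SD, and a two-condition t-test.

    ``data`` holds one row per membrane sheet with condition, replicate
    and metric columns; exactly two conditions are compared. The test
    is Student's two-sided unpaired t-test on the replicate means
    (equal variance by default; ``welch=True`` drops that assumption).
    """
    conditions = sorted(data[condition].unique().tolist())
    if len(conditions) != 2:
        raise ValidationError(f"need exactly 2 conditions, got {conditions}")
    per_rep = data.groupby([condition, replicate])[value].mean()
    means = {c: per_rep.loc[c].to_numpy() for c in conditions}
    for c in conditions:
        if len(means[c]) < 2:
            raise ValidationError(
                f"condition {c!r} has a single replicate; SD is undefined"
            )
    a, b = conditions
    tstat, p = sps.ttest_ind(means[a], means[b], equal_var=not welch)
    return ReplicateSummary(
        a, b, means[a], means[b],
        float(means[a].mean()), float(means[b].mean()),
        float(means[a].std(ddof=1)), float(means[b].std(ddof=1)),
        float(tstat), float(p), star_code(float(p)),
    )
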