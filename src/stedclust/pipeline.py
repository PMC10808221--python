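"""End-to-end two-channel analysis.

``run_pipeline`` chains the full procedure on one image pair:
optional crosstalk correction → Gaussian blur → maxima detection in
both channels → per-maximum quantification and cluster classification
→ directional shortest-distance/overlap analysis → same-channel
crowding counts → densities and through-origin intensity regressions.
The run is fully deterministic in its inputs; ``write_results`` dumps
every table plus a checksummed manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisParams
from .detect import correct_crosstalk, find_maxima, gaussian_blur
from .errors import ValidationError
from .image import PixelImage, check_same_grid
from .io import write_csv, write_json
from .quantify import measure_maxima, roi_mean
from .spatial import (
    DistanceResult,
    NeighborCounts,
    cluster_density,
    interior_mask,
    neighbor_counts,
    overlap_fraction,
    shortest_cross_distances,
)
from .stats import OriginRegression, origin_regression


@dataclass
class ChannelResult:
    """Everything measured on one channel's maxima."""

    channel: str
    maxima: pd.DataFrame
    neighbor_counts: NeighborCounts
    density_per_um2: float
    regression: OriginRegression | None


@dataclass
class PipelineResult:
    """Result bundle of one two-channel run."""

    channel_a: ChannelResult
    channel_b: ChannelResult
    distances_ab: DistanceResult | None
    distances_ba: DistanceResult | None
    area_um2: float
    params: AnalysisParams

    def summary(self) -> pd.DataFrame:
        def pct(res: DistanceResult | None) -> float:
            return 100.0 * overlap_fraction(res) if res is not None and len(res) else np.nan

        rows = []
        for ch, dist in ((self.channel_a, self.distances_ab), (self.channel_b, self.distances_ba)):
            counts = ch.neighbor_counts.counts
            rows.append(
                {
                    "channel": ch.channel,
                    "n_maxima": len(ch.maxima),
                    "n_clusters": int(ch.maxima["is_cluster"].sum()) if len(ch.maxima) else 0,
                    "density_per_um2": ch.density_per_um2,
                    "overlap_pct": pct(dist),
                    "mean_neighbors": float(counts.mean()) if len(counts) else np.nan,
                    "regression_slope": ch.regression.slope if ch.regression else np.nan,
                    "regression_r2": ch.regression.r2 if ch.regression else np.nan,
                    "frac_both_pct": 100.0 * ch.regression.frac_both if ch.regression else np.nan,
                    "area_um2": self.area_um2,
                }
            )
        return pd.DataFrame(rows)


def _background_for(
    img: PixelImage, params: AnalysisParams
) -> float:
    if params.background_roi is not None:
        return roi_mean(img, tuple(params.background_roi), params.roi_diameter_px)
    if img.channel is not None and img.channel in params.background_au:
        return params.background_au[img.channel]
    return 0.0


def _analyze_channel(
    img_self: PixelImage,
    img_other: PixelImage,
    params: AnalysisParams,
    area_um2: float,
    mask: np.ndarray | None,
) -> ChannelResult:
    tol = params.tolerance_for(img_self.channel)
    maxima = find_maxima(img_self, tol, params.exclude_edge_maxima)
    if mask is not None and len(maxima):
        on_sheet = mask[maxima.positions[:, 0], maxima.positions[:, 1]]
        maxima.positions = maxima.positions[on_sheet]
    bg_self = _background_for(img_self, params)
    bg_other = _background_for(img_other, params)
    table = measure_maxima(img_self, img_other, maxima, params, bg_self, bg_other)

    pos_nm = maxima.positions_nm(img_self.pixel_size_nm)
    counts = neighbor_counts(pos_nm, params.neighbor_diameter_nm)
    if params.edge_correct_neighbors and len(counts):
        h, w = img_self.shape
        field = (w * img_self.pixel_size_nm, h * img_self.pixel_size_nm)
        keep = interior_mask(pos_nm, field, params.neighbor_diameter_nm / 2.0)
        counts = NeighborCounts(counts.counts[keep], counts.circle_diameter_nm)

    density = cluster_density(int(table["is_cluster"].sum()), area_um2)
    regression = None
    valid = table.dropna(subset=["intensity_self", "intensity_other"]) if len(table) else table
    if len(valid) >= 2:
        regression = origin_regression(
            valid["intensity_self"], valid["intensity_other"], params.noise_level_au
        )
    return ChannelResult(img_self.channel or "?", table, counts, density, regression)


def run_pipeline(
    ch_self: PixelImage,
    ch_other: PixelImage,
    params: AnalysisParams | None = None,
    mask: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full analysis on one channel pair.

    ``ch_self`` plays the role of channel A (e.g. the red channel),
    ``ch_other`` of channel B (the long-red channel); crosstalk
    correction, when configured, subtracts ``crosstalk_factor`` times
    one channel from the other before anything else.
    """
    params = params or AnalysisParams()
    check_same_grid(ch_self, ch_other)
    if mask is not None and mask.shape != ch_self.shape:
        raise ValidationError("mask shape does not match the images")

    if params.crosstalk_apply == "other_minus_self":
        ch_other = correct_crosstalk(ch_other, ch_self, params.crosstalk_factor)
    elif params.crosstalk_apply == "self_minus_other":
        ch_self = correct_crosstalk(ch_self, ch_other, params.crosstalk_factor)

    blur_a = gaussian_blur(ch_self, params.blur_sigma_px)
    blur_b = gaussian_blur(ch_other, params.blur_sigma_px)

    px_um2 = (ch_self.pixel_size_nm / 1000.0) ** 2
    area_um2 = float(mask.sum()) * px_um2 if mask is not None else ch_self.area_um2

    res_a = _analyze_channel(blur_a, blur_b, params, area_um2, mask)
    res_b = _analyze_channel(blur_b, blur_a, params, area_um2, mask)

    def cluster_xy(table: pd.DataFrame) -> np.ndarray:
        return table.loc[table["is_cluster"], ["x_nm", "y_nm"]].to_numpy()

    xy_a, xy_b = cluster_xy(res_a.maxima), cluster_xy(res_b.maxima)
    dist_ab = dist_ba = None
    if len(xy_a) and len(xy_b):
        dist_ab = shortest_cross_distances(xy_a, xy_b, params.overlap_threshold_nm)
        dist_ba = shortest_cross_distances(xy_b, xy_a, params.overlap_threshold_nm)
    return PipelineResult(res_a, res_b, dist_ab, dist_ba, area_um2, params)


def write_results(result: PipelineResult, outdir: str | Path, inputs: dict | None = None) -> dict:
    """Write all result tables and a manifest with output checksums."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    for ch in (result.channel_a, result.channel_b):
        name = f"maxima_{ch.channel}.csv"
        checksums[name] = write_csv(ch.maxima, outdir / name)
        nb = pd.DataFrame(
            {"maximum_id": np.arange(len(ch.neighbor_counts)), "count": ch.neighbor_counts.counts}
        )
        name = f"neighbors_{ch.channel}.csv"
        checksums[name] = write_csv(nb, outdir / name)

    for label, dist in (("ab", result.distances_ab), ("ba", result.distances_ba)):
        if dist is None:
            df = pd.DataFrame(columns=["src_id", "nn_distance_nm", "overlap"])
        else:
            df = pd.DataFrame(
                {
                    "src_id": np.arange(len(dist)),
                    "nn_distance_nm": dist.distances_nm,
                    "overlap": dist.overlap_flags,
                }
            )
        checksums[f"distances_{label}.csv"] = write_csv(df, outdir / f"distances_{label}.csv")

    checksums["summary.csv"] = write_csv(result.summary(), outdir / "summary.csv")

    corr_rows = []
    for ch in (result.channel_a, result.channel_b):
        if ch.regression is None:
            continue
        r = ch.regression
        corr_rows.append(
            {
                "channel": ch.channel,
                "slope": r.slope,
                "r2": r.r2,
                "n": r.n,
                "frac_both": r.frac_both,
                "frac_self_only": r.frac_self_only,
                "frac_below_noise": r.frac_below_noise,
            }
        )
    checksums["correlation.csv"] = write_csv(pd.DataFrame(corr_rows), outdir / "correlation.csv")

    manifest = {
        "software": {"name": "stedclust", "version": __version__},
        "inputs": inputs or {},
        "params": result.params.model_dump(),
        "outputs": checksums,
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
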