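"""Synthetic two-channel membrane-sheet images with ground truth.

The generator emulates STED micrographs of immunostained membrane
sheets: diffraction-limited spots of variable brightness scattered over
a flat sheet, with a tunable fraction of assemblies carrying both
channel labels (co-assembly) and an optional fraction agglomerated into
µm-scale "arranged crowds".

Point process
    A fraction ``1 - crowd_fraction`` of assemblies is drawn from
    complete spatial randomness (homogeneous Poisson) at
    ``density_per_um2``. The crowded fraction follows a Thomas-type
    parent-child process: crowd centres are themselves CSR, each crowd
    holds Poisson(``assemblies_per_crowd``) children scattered with an
    isotropic Gaussian of scale ``crowd_radius_nm``; children falling
    outside the field are discarded, so the realized density is
    slightly edge-deflated.

Composition and brightness
    Channel membership (A-only / B-only / both) is i.i.d. from the
    configured fractions. Integrated spot brightness is log-normal per
    channel; the two amplitudes of a "both" assembly are drawn
    independently (no built-in inter-channel intensity correlation).
    Per channel, each spot is kept for rendering with probability
    ``detect_prob`` (labelling efficiency / epitope shielding); dropped
    spots stay in the truth table with ``det_* = False``.

Image formation
    Each detected spot is an isotropic Gaussian of the configured PSF
    full width at half maximum, integrated exactly over the pixel grid
    (erf differences), on a constant background. Recorded pixels are
    Poisson(signal + background) plus Gaussian readout noise, clipped
    at zero and quantized to 16 bit. Everything is deterministic in
    the config seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

from .config import SimConfig
from .errors import InputOutputError, ValidationError
from .image import PixelImage

TRUTH_COLUMNS = [
    "id", "x_nm", "y_nm", "membership", "amp_a", "amp_b", "crowd_id", "det_a", "det_b",
]


@dataclass
class GroundTruth:
    """Simulator truth: one row per assembly, keyed to the rendered images."""

    table: pd.DataFrame
    config: SimConfig

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"truth table misses columns {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def positions_nm(self, channel: str, detected_only: bool = True) -> np.ndarray:
        """(x, y) nm of assemblies carrying the channel (optionally detected)."""
        t = self._channel_rows(channel)
        if detected_only:
            t = t[t[f"det_{channel.lower()}"]]
        return t[["x_nm", "y_nm"]].to_numpy()

    def _channel_rows(self, channel: str) -> pd.DataFrame:
        if channel not in ("A", "B"):
            raise ValidationError(f"channel must be 'A' or 'B', got {channel!r}")
        key = "a_only" if channel == "A" else "b_only"
        return self.table[self.table["membership"].isin(["both", key])]


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and SD."""
    if sd == 0:
        return np.full(size, mean)
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size)


def sample_positions(config: SimConfig) -> GroundTruth:
    """Draw assembly positions, composition, crowding and detection flags."""
    rng = np.random.default_rng([config.seed, 0x5EED])
    width_nm, height_nm = config.field_size_nm
    lam_total = config.density_per_um2 * config.area_um2  # expected assemblies

    # scattered (CSR) part
    n_bg = rng.poisson(lam_total * (1.0 - config.crowd_fraction))
    xs = [rng.uniform(0.0, width_nm, n_bg)]
    ys = [rng.uniform(0.0, height_nm, n_bg)]
    crowd_ids = [np.full(n_bg, -1, dtype=np.int64)]

    # crowded (Thomas) part: parent centres CSR, children Gaussian-scattered
    if config.crowd_fraction > 0:
        n_parents = rng.poisson(
            lam_total * config.crowd_fraction / config.assemblies_per_crowd
        )
        for pid in range(n_parents):
            cx = rng.uniform(0.0, width_nm)
            cy = rng.uniform(0.0, height_nm)
            n_child = rng.poisson(config.assemblies_per_crowd)
            child_x = cx + rng.normal(0.0, config.crowd_radius_nm, n_child)
            child_y = cy + rng.normal(0.0, config.crowd_radius_nm, n_child)
            keep = (
                (child_x >= 0) & (child_x < width_nm)
                & (child_y >= 0) & (child_y < height_nm)
            )
            xs.append(child_x[keep])
            ys.append(child_y[keep])
            crowd_ids.append(np.full(int(keep.sum()), pid, dtype=np.int64))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    crowd_id = np.concatenate(crowd_ids)
    n = len(x)

    membership = rng.choice(
        ["both", "a_only", "b_only"],
        size=n,
        p=[config.frac_both, config.frac_a_only, config.frac_b_only],
    )
    amp_a = _lognormal(rng, config.amplitude_mean_a, config.amplitude_sd_a, n)
    amp_b = _lognormal(rng, config.amplitude_mean_b, config.amplitude_sd_b, n)
    has_a = np.isin(membership, ["both", "a_only"])
    has_b = np.isin(membership, ["both", "b_only"])
    amp_a[~has_a] = 0.0
    amp_b[~has_b] = 0.0
    det_a = has_a & (rng.uniform(size=n) < config.detect_prob)
    det_b = has_b & (rng.uniform(size=n) < config.detect_prob)

    table = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "x_nm": x,
            "y_nm": y,
            "membership": membership,
            "amp_a": amp_a,
            "amp_b": amp_b,
            "crowd_id": crowd_id,
            "det_a": det_a,
            "det_b": det_b,
        }
    )
    return GroundTruth(table, config)


def render_signal(truth: GroundTruth, config: SimConfig, channel: str) -> np.ndarray:
    """Noiseless expected photon image of one channel (no background).

    Each detected spot contributes an isotropic Gaussian of FWHM
    ``psf_fwhm_nm`` whose integral over the full plane equals the drawn
    amplitude; pixel values are exact integrals over the pixel squares.
    """
    if channel not in ("A", "B"):
        raise ValidationError(f"channel must be 'A' or 'B', got {channel!r}")
    h, w = config.image_size_px
    p = config.pixel_size_nm
    sigma = config.psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = truth.table
    col = channel.lower()
    rows = t[(t[f"amp_{col}"] > 0) & t[f"det_{col}"]]
    signal = np.zeros((h, w), dtype=np.float64)
    half = int(np.ceil(5.0 * sigma / p)) + 1
    sq2s = np.sqrt(2.0) * sigma
    for x0, y0, amp in zip(rows["x_nm"], rows["y_nm"], rows[f"amp_{col}"]):
        cx, cy = int(x0 // p), int(y0 // p)
        c0, c1 = max(cx - half, 0), min(cx + half + 1, w)
        r0, r1 = max(cy - half, 0), min(cy + half + 1, h)
        if c0 >= c1 or r0 >= r1:
            continue
        ex = erf((np.arange(c0, c1 + 1) * p - x0) / sq2s)
        ey = erf((np.arange(r0, r1 + 1) * p - y0) / sq2s)
        gx = 0.5 * np.diff(ex)
        gy = 0.5 * np.diff(ey)
        signal[r0:r1, c0:c1] += amp * np.outer(gy, gx)
    return signal


def render_image(truth: GroundTruth, config: SimConfig, channel: str) -> PixelImage:
    """Render one channel with shot noise, readout noise and quantization."""
    signal = render_signal(truth, config, channel)
    rng = np.random.default_rng([config.seed, 0x1A6E, 0 if channel == "A" else 1])
    photons = rng.poisson(signal + config.background_offset).astype(np.float64)
    if config.read_noise_sd > 0:
        photons += rng.normal(0.0, config.read_noise_sd, photons.shape)
    counts = np.clip(np.rint(photons), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return PixelImage(counts.astype(np.float64), config.pixel_size_nm, channel)


def sample_crowding_counts(
    n: int,
    crowded_fraction: float,
    mean_background: float = 3.5,
    sd_background: float = 1.8,
    mean_crowded: float = 12.0,
    sd_crowded: float = 3.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Neighboured-maxima counts from a two-normal mixture.

    Ground truth for the mixture-decomposition analysis: a background
    population of sparsely neighboured maxima and a crowded population
    with several-fold more neighbours. Draws are rounded to the nearest
    non-negative integer, as real counts are.
    """
    if not 0.0 <= crowded_fraction <= 1.0:
        raise ValidationError("crowded_fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    crowded = rng.uniform(size=n) < crowded_fraction
    vals = np.where(
        crowded,
        rng.normal(mean_crowded, sd_crowded, n),
        rng.normal(mean_background, sd_background, n),
    )
    return np.clip(np.rint(vals), 0, None).astype(np.int64)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise ValidationError(f"cannot serialize {type(value).__name__} to TOML")


def config_to_toml(config: SimConfig) -> str:
    lines = []
    for key, value in config.model_dump().items():
        lines.append(f"{key} = {_toml_scalar(value)}")
    return "\n".join(lines) + "\n"


def write_dataset(
    truth: GroundTruth,
    images: dict[str, PixelImage],
    outdir: str | Path,
) -> dict:
    """Write TIFFs, truth table, config echo and a checksum manifest.

    Returns the manifest dict (also saved as ``manifest.json``).
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputOutputError(f"cannot create {outdir}: {exc}") from exc
    files: dict[str, str] = {}
    try:
        for channel, img in sorted(images.items()):
            name = f"channel_{channel}.tif"
            tifffile.imwrite(
                outdir / name, img.values.astype(np.uint16), photometric="minisblack"
            )
            files[name] = _sha256(outdir / name)
        truth.table.to_csv(outdir / "truth.csv", index=False)
        files["truth.csv"] = _sha256(outdir / "truth.csv")
        (outdir / "config.toml").write_text(config_to_toml(truth.config))
        files["config.toml"] = _sha256(outdir / "config.toml")
    except OSError as exc:
        raise InputOutputError(f"cannot write dataset to {outdir}: {exc}") from exc
    manifest = {
        "seed": truth.config.seed,
        "n_assemblies": int(len(truth)),
        "files": files,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
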