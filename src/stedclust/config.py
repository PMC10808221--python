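"""Validated configuration objects.

Two configs drive everything:

* :class:`SimConfig` — the synthetic membrane-sheet generator. Defaults
  describe the imaging conditions the analysis was designed for:
  4 assemblies/µm² per channel, a STED point-spread function of
  65–100 nm full width at half maximum (default 80 nm), 20 nm pixels,
  log-normally distributed spot brightness, Poisson photon noise on a
  constant membrane background plus Gaussian readout noise.

* :class:`AnalysisParams` — every numeric constant of the analysis
  pipeline (blur sigma, per-antibody noise tolerances, ROI and linescan
  geometry, the R² and centered-peak cluster criteria, the 60 nm overlap
  threshold, the 900 nm crowding circle, the 2 a.u. noise gate, the 50%
  crosstalk factor). Defaults reproduce the published settings, so an
  empty override file runs the canonical analysis.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import pydantic
from pydantic import BaseModel, Field, model_validator

from .errors import ValidationError

#: Noise tolerance of the maxima finder per antibody target, in a.u.
DEFAULT_NOISE_TOLERANCES: dict[str, float] = {
    "CD9": 4.0,
    "CD81": 4.0,
    "CD151": 4.0,
    "CD44": 8.0,
    "pERM": 5.0,
    "EWI-2": 6.0,
}

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # FWHM = factor * sigma


class _StrictModel(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", validate_assignment=True)

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except pydantic.ValidationError as exc:  # re-raise under our hierarchy
            raise ValidationError(str(exc)) from exc


class SimConfig(_StrictModel):
    """Parameters of the two-channel membrane-sheet simulator."""

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = Field(20.0, gt=0)
    #: total assembly density; with the default composition each channel
    #: carries ~0.7x this, i.e. ~4.2/µm² of channel-bearing assemblies
    density_per_um2: float = Field(6.0, gt=0)
    frac_both: float = Field(0.4, ge=0, le=1)
    frac_a_only: float = Field(0.3, ge=0, le=1)
    frac_b_only: float = Field(0.3, ge=0, le=1)
    #: fraction of assemblies placed inside arranged crowds (Thomas process)
    crowd_fraction: float = Field(0.0, ge=0, le=1)
    crowd_radius_nm: float = Field(450.0, gt=0)
    assemblies_per_crowd: float = Field(12.0, gt=0)
    #: mean/sd of the log-normal integrated spot brightness, per channel
    amplitude_mean_a: float = Field(3000.0, gt=0)
    amplitude_sd_a: float = Field(1500.0, ge=0)
    amplitude_mean_b: float = Field(3000.0, gt=0)
    amplitude_sd_b: float = Field(1500.0, ge=0)
    psf_fwhm_nm: float = Field(80.0, gt=0)
    background_offset: float = Field(2.0, ge=0)
    read_noise_sd: float = Field(1.0, ge=0)
    #: per-spot, per-channel labelling/detection probability (epitope shielding)
    detect_prob: float = Field(1.0, gt=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.image_size_px[0] <= 0 or self.image_size_px[1] <= 0:
            raise ValueError("image_size_px must be positive")
        total = self.frac_both + self.frac_a_only + self.frac_b_only
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"composition fractions must sum to 1 (got {total:.6g})"
            )
        for name in (
            "pixel_size_nm", "density_per_um2", "crowd_radius_nm",
            "assemblies_per_crowd", "amplitude_mean_a", "amplitude_sd_a",
            "amplitude_mean_b", "amplitude_sd_b", "psf_fwhm_nm",
            "background_offset", "read_noise_sd",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        return self

    @property
    def field_size_nm(self) -> tuple[float, float]:
        """(width, height) of the field in nm, x along columns."""
        h, w = self.image_size_px
        return w * self.pixel_size_nm, h * self.pixel_size_nm

    @property
    def area_um2(self) -> float:
        h, w = self.image_size_px
        return h * w * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm / FWHM_FACTOR / self.pixel_size_nm


class AnalysisParams(_StrictModel):
    """Parameters of the cluster-analysis pipeline (defaults = published values)."""

    pixel_size_nm: float = Field(20.0, gt=0)
    blur_sigma_px: float = Field(0.5, ge=0)
    noise_tolerance: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_NOISE_TOLERANCES)
    )
    default_noise_tolerance: float = Field(4.0, gt=0)
    roi_diameter_px: int = Field(5, gt=0)
    linescan_length_px: int = Field(31, gt=0)
    linescan_width_px: int = Field(3, gt=0)
    r2_threshold: float = Field(0.8, gt=0, lt=1)
    center_window_px: float = Field(5.0, gt=0)
    overlap_threshold_nm: float = Field(60.0, gt=0)
    neighbor_diameter_nm: float = Field(900.0, gt=0)
    noise_level_au: float = Field(2.0, ge=0)
    crosstalk_factor: float = Field(0.5, ge=0, le=1)
    #: which channel receives the crosstalk subtraction, if any
    crosstalk_apply: Literal["none", "other_minus_self", "self_minus_other"] = "none"
    distance_bin_nm: float = Field(10.0, gt=0)
    #: (row, col) of the background ROI centre, next to the membrane sheet
    background_roi: Optional[tuple[int, int]] = None
    #: explicit background level per channel label, used when no ROI is given
    background_au: dict[str, float] = Field(default_factory=dict)
    #: drop maxima that sit on the outermost pixel row/column
    exclude_edge_maxima: bool = False
    #: exclude maxima within neighbor radius of the border from crowding stats
    edge_correct_neighbors: bool = False

    @model_validator(mode="after")
    def _check(self) -> "AnalysisParams":
        if self.linescan_length_px % 2 != 1:
            raise ValueError("linescan_length_px must be odd")
        if self.linescan_width_px % 2 != 1:
            raise ValueError("linescan_width_px must be odd")
        for label, tol in self.noise_tolerance.items():
            if not (math.isfinite(tol) and tol > 0):
                raise ValueError(f"noise tolerance for {label!r} must be > 0")
        return self

    def tolerance_for(self, channel: str | None) -> float:
        """Noise tolerance for a channel label, falling back to the default."""
        if channel is not None and channel in self.noise_tolerance:
            return self.noise_tolerance[channel]
        return self.default_noise_tolerance

    @property
    def linescan_half_px(self) -> int:
        return self.linescan_length_px // 2

    @property
    def center_index(self) -> int:
        return self.linescan_length_px // 2
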