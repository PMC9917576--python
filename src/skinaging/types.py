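"""Core value types shared across the pipeline.

All rasters are numpy arrays indexed (row, col), 0-based. Physical units are
millimetres, converted through a single calibration constant ``mm_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import imageio.v3 as iio
import numpy as np

from .errors import DataError

#: Object classes recognised by the classification rules, in precedence order.
OBJECT_CLASSES = ("wrinkle", "spot", "pore", "texture")

#: Label returned for candidate objects matching no rule set.
UNCLASSIFIED = "none"


@dataclass
class SkinImage:
    """A calibrated RGB skin image.

    Parameters
    ----------
    rgb : ndarray, shape (rows, cols, 3), float in [0, 1]
        sRGB pixel data (D65). Kept in float to avoid quantization of the
        colour-difference signal; quantization to 8/16-bit happens only on
        export.
    mm_per_px : float
        Pixel pitch in millimetres. All mm-denominated rules convert
        through this constant.
    roi : ndarray of bool, optional
        Region-of-interest mask; ``None`` means the full frame.
    """

    rgb: np.ndarray
    mm_per_px: float
    roi: np.ndarray | None = None

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            nchan = self.rgb.shape[2] if self.rgb.ndim == 3 else self.rgb.ndim
            raise DataError(f"expected an RGB raster with 3 channels, got {nchan}")
        if not self.mm_per_px > 0:
            raise DataError(f"mm_per_px must be positive, got {self.mm_per_px}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]

    def roi_mask(self) -> np.ndarray:
        if self.roi is not None:
            return np.asarray(self.roi, dtype=bool)
        return np.ones(self.shape, dtype=bool)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, mm_per_px: float,
                  roi: np.ndarray | None = None) -> "SkinImage":
        raw = iio.imread(path)
        if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
            raw = raw[..., :3]
        if raw.dtype == np.uint8:
            rgb = raw.astype(float) / 255.0
        elif raw.dtype == np.uint16:
            rgb = raw.astype(float) / 65535.0
        else:
            rgb = np.asarray(raw, dtype=float)
        return cls(rgb=rgb, mm_per_px=mm_per_px, roi=roi)

    def to_file(self, path: str | Path, bit_depth: int = 8) -> None:
        """Write as 8-bit PNG or 16-bit TIFF depending on ``bit_depth``."""
        clipped = np.clip(self.rgb, 0.0, 1.0)
        if bit_depth == 8:
            iio.imwrite(path, (clipped * 255.0 + 0.5).astype(np.uint8))
        elif bit_depth == 16:
            iio.imwrite(path, (clipped * 65535.0 + 0.5).astype(np.uint16))
        else:
            raise DataError(f"unsupported bit depth {bit_depth}; use 8 or 16")


@dataclass
class PlantedObject:
    """Ground truth for one synthetic object rendered into an image."""

    object_class: str
    mask: np.ndarray  # full-frame bool raster, single 8-connected component
    nominal_area_mm2: float
    nominal_delta_e: float
    center: tuple[float, float]  # (row, col), px
    nominal_length_mm: float | None = None  # wrinkles only
    nominal_circularity: float | None = None
    nominal_aspect_ratio: float | None = None

    def __post_init__(self):
        if self.object_class not in OBJECT_CLASSES:
            raise DataError(f"unknown object class {self.object_class!r}")
        if not self.nominal_area_mm2 > 0:
            raise DataError("nominal_area_mm2 must be positive")
        if self.nominal_delta_e < 0:
            raise DataError("nominal_delta_e must be non-negative")


class ColorSummary(NamedTuple):
    """ROI colour summary: mean CIELAB coordinates."""

    lightness: float  # mean L*
    redness: float    # mean a*
    yellowness: float  # mean b*


@dataclass
class ObjectMeasurements:
    """Shape and contrast descriptors of one connected candidate object."""

    label: int
    area_px: int
    area_mm2: float
    perimeter_px: float
    length_mm: float
    aspect_ratio: float
    circularity: float
    surround_delta_e: float
    perimeter_length_ratio: float
    degenerate: bool = False
    touches_border: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FeatureFractions:
    """Per-image area fractions and ROI colour, the unit of cohort scoring.

    ``pore_fraction`` carries the conventional x3 multiplier and therefore
    lives in [0, 3]; the other fractions live in [0, 1].
    """

    wrinkle_fraction: float
    spot_fraction: float
    texture_fraction: float
    pore_fraction: float
    lightness: float
    redness: float
    yellowness: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ReversalEstimate:
    """Reversal years of skin aging for one subject at one timepoint.

    ``years`` is 0 when the evaluated score equals the pre-treatment score
    and -interval_years when it equals the decade-earlier baseline score.
    """

    years: float
    numerator_delta: float
    denominator_delta: float
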