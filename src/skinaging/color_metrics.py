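"""CIELAB conversion, CIE76 colour difference and surround-contrast metrics.

All colour arithmetic in the pipeline happens in CIELAB (D65, 2° observer,
sRGB primaries assumed on input). ``delta_e`` is the CIE76 Euclidean
distance; "lightness", "redness" and "yellowness" map to the L*, a* and b*
axes respectively.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

from .errors import DataError
from .types import ColorSummary, SkinImage

__all__ = ["rgb_to_lab", "lab_to_rgb", "delta_e", "surround_contrast",
           "roi_color_summary"]


def rgb_to_lab(image: SkinImage | np.ndarray) -> np.ndarray:
    """Convert an sRGB image to CIELAB, per pixel.

    Accepts a :class:`SkinImage` or a raw array (uint8, uint16, or float in
    [0, 1]). Returns a float array of shape (rows, cols, 3) holding
    (L*, a*, b*).
    """
    rgb = image.rgb if isinstance(image, SkinImage) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        nchan = rgb.shape[2] if rgb.ndim == 3 else rgb.ndim
        raise DataError(f"expected an RGB raster with 3 channels, got {nchan}")
    if rgb.dtype == np.uint8:
        rgb = rgb.astype(float) / 255.0
    elif rgb.dtype == np.uint16:
        rgb = rgb.astype(float) / 65535.0
    return _skcolor.rgb2lab(rgb)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    """Inverse transform; returns float sRGB clipped to [0, 1]."""
    return np.clip(_skcolor.lab2rgb(np.asarray(lab, dtype=float)), 0.0, 1.0)


def delta_e(lab_a, lab_b) -> float | np.ndarray:
    """CIE76 colour difference: Euclidean distance in L*a*b*.

    Broadcasts over leading dimensions, so it accepts single triplets or
    whole images. Total on finite input.
    """
    a = np.asarray(lab_a, dtype=float)
    b = np.asarray(lab_b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("delta_e requires finite Lab coordinates")
    d = np.linalg.norm(a - b, axis=-1)
    return float(d) if d.ndim == 0 else d


def _disk(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= r * r


def surround_contrast(lab: np.ndarray, object_mask: np.ndarray,
                      ring_width_mm: float, mm_per_px: float,
                      exclude_mask: np.ndarray | None = None) -> float:
    """ΔE between an object and a surrounding annulus of skin.

    The annulus is ``dilate(mask) − mask`` with a disk of radius
    ``ring_width_mm``; pixels belonging to other detected objects
    (``exclude_mask``) are removed from the ring so nested or nearby objects
    do not contaminate the background estimate.
    """
    mask = np.asarray(object_mask, dtype=bool)
    if not mask.any():
        raise DataError("surround_contrast: empty object mask")
    if mask.shape != lab.shape[:2]:
        raise DataError("object mask geometry does not match the Lab raster")
    if not ring_width_mm > 0:
        raise DataError("ring_width_mm must be positive")
    radius = max(1, int(round(ring_width_mm / mm_per_px)))
    dilated = ndimage.binary_dilation(mask, structure=_disk(radius))
    ring = dilated & ~mask
    if exclude_mask is not None:
        ring &= ~np.asarray(exclude_mask, dtype=bool)
    if not ring.any():
        raise DataError(
            "surround_contrast: annulus empty (object surrounded by image "
            "border or excluded pixels)")
    inner = lab[mask].mean(axis=0)
    outer = lab[ring].mean(axis=0)
    return float(np.linalg.norm(inner - outer))


def roi_color_summary(lab: np.ndarray, roi: np.ndarray) -> ColorSummary:
    """Mean L*, a*, b* over the region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise DataError("roi_color_summary: empty ROI")
    vals = lab[roi]
    return ColorSummary(lightness=float(vals[:, 0].mean()),
                        redness=float(vals[:, 1].mean()),
                        yellowness=float(vals[:, 2].mean()))
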