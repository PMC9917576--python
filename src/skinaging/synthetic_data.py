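"""Ground-truthed synthetic skin images and longitudinal cohorts.

Images
------
A uniform CIELAB skin background (defaults matching a measured healthy-skin
colour: L*=59.27, a*=12.55, b*=20.39) with i.i.d. Gaussian noise on L* only
(luminance dominates real skin texture; keeping a*/b* smooth makes planted
ΔE controllable). Objects are rendered as constant L*a*b* offsets of a
requested CIE76 magnitude:

* wrinkles - constant-width dark strokes along circular-arc paths of a
  stated arc length;
* spots / pores - elliptical blobs whose boundary may carry a sinusoidal
  radial modulation, raising perimeter²/area to the irregular-boundary
  values real hyperpigmented spots show;
* texture elements - small smooth ellipses.

Rendering happens in Lab and is converted to sRGB once, so planted contrast
survives exactly (images are float; quantization only happens on export).

Cohorts
-------
Per subject, a latent *aging severity* drives the correlated deterioration
of all parameters between the decade-earlier baseline and the pre-treatment
visit (both drawn with the stated means/SDs), and a latent *treatment
response* factor is shared between the hydration change and the outcome
changes under treatment, with its loadings solved so that the population
Pearson r between Δhydration and each Δoutcome (last visit − pre-treatment)
equals the requested target exactly. Treatment visits interpolate from the
pre-treatment value back toward the subject's own baseline value by a
per-visit recovery fraction, plus noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .color_metrics import lab_to_rgb, rgb_to_lab
from .errors import ConfigurationError, DataError, PlacementError
from .types import OBJECT_CLASSES, PlantedObject, SkinImage

__all__ = ["ImageSpec", "ObjectRequest", "CohortSpec", "REFERENCE_COHORT_CALIBRATION",
           "generate_labeled_image", "plant_wrinkle", "plant_blob",
           "generate_cohort", "default_object_params",
           "solve_boundary_amplitude", "write_image_outputs"]


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class ObjectRequest:
    """Request for ``count`` objects of one class.

    ``params`` maps parameter names to either a fixed value or a (lo, hi)
    range sampled uniformly per object; omitted parameters fall back to
    :func:`default_object_params`.
    """

    object_class: str
    count: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.object_class not in OBJECT_CLASSES:
            raise ConfigurationError(
                f"unknown object class {self.object_class!r}")
        if self.count < 0:
            raise ConfigurationError("object count must be >= 0")


@dataclass
class ImageSpec:
    """Specification of one synthetic labelled image."""

    size_px: tuple[int, int] = (256, 256)
    mm_per_px: float = 0.1
    background_lab: tuple[float, float, float] = (59.27, 12.55, 20.39)
    background_noise_sd: float = 0.5
    object_requests: list[ObjectRequest] = field(default_factory=list)
    seed: int = 0
    isolated: bool = True
    min_separation_px: int = 20
    margin_mm: float = 1.5
    max_attempts: int = 1000

    def __post_init__(self):
        self.object_requests = [
            r if isinstance(r, ObjectRequest) else ObjectRequest(*r)
            for r in self.object_requests]
        if not self.mm_per_px > 0:
            raise ConfigurationError("mm_per_px must be positive")
        if self.background_noise_sd < 0:
            raise ConfigurationError("background_noise_sd must be >= 0")


#: Per-parameter (mean, SD) calibration at the decade-earlier baseline and
#: the pre-treatment visit, matching the measured 86-subject cohort.
REFERENCE_COHORT_CALIBRATION: dict[str, tuple[float, float, float, float]] = {
    #               mean_baseline sd   mean_pretreat sd
    "hydration":   (56.71, 7.11, 47.76, 8.68),
    "tewl":        (12.34, 3.83, 13.36, 3.18),
    "wrinkles":    (0.20, 0.18, 0.37, 0.28),
    "spots":       (0.19, 0.11, 0.28, 0.15),
    "roughness":   (0.73, 0.40, 0.86, 0.42),
    "lightness":   (59.27, 2.69, 57.60, 2.45),
    "redness":     (12.55, 1.92, 12.43, 1.54),
    "yellowness":  (20.39, 1.93, 21.63, 1.93),
    "pore_size":   (0.0157, 0.0122, 0.0202, 0.011),
    "sebum":       (36.73, 29.94, 38.68, 34.11),
    "elasticity":  (0.28, 0.05, 0.24, 0.06),
}


def _default_recovery() -> dict[str, float]:
    # fractions of the 11-year deterioration recovered at each visit,
    # chosen to mirror the reported reversal trajectory (~-4.7, -7.0,
    # -9.2 years out of -11)
    return {"2M": 0.43, "8M": 0.64, "12M": 0.84}


@dataclass
class CohortSpec:
    """Specification of a longitudinal synthetic cohort."""

    n_subjects: int = 86
    timepoints: tuple[str, ...] = ("1999", "0M", "2M", "8M", "12M")
    parameters: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(REFERENCE_COHORT_CALIBRATION))
    recovery_fraction: dict[str, float] = field(
        default_factory=_default_recovery)
    response_correlation: float = -0.32
    response_parameters: tuple[str, ...] = ("tewl", "wrinkles", "spots",
                                            "roughness")
    hydration_parameter: str = "hydration"
    baseline_correlation: float = 0.7
    severity_loading: float = 0.6
    hydration_response_sd_frac: float = 0.3
    hydration_response_share: float = 0.9
    outcome_noise_frac: float = 0.2
    seed: int = 0

    @property
    def baseline_timepoint(self) -> str:
        return self.timepoints[0]

    @property
    def pretreat_timepoint(self) -> str:
        return self.timepoints[1]

    @property
    def treatment_timepoints(self) -> tuple[str, ...]:
        return tuple(self.timepoints[2:])

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if len(self.timepoints) < 2:
            raise ConfigurationError(
                "need at least the baseline and pre-treatment timepoints")
        for p, (m99, s99, m0, s0) in self.parameters.items():
            if not (s99 > 0 and s0 > 0):
                raise ConfigurationError(f"SDs for {p!r} must be positive")
        if not abs(self.response_correlation) < 1:
            raise ConfigurationError("|response_correlation| must be < 1")
        fracs = [self.recovery_fraction[tp]
                 for tp in self.treatment_timepoints
                 if tp in self.recovery_fraction]
        for a, b in zip(fracs, fracs[1:]):
            if b < a:
                raise ConfigurationError(
                    "recovery_fraction must be nondecreasing over visits")
        for tp in self.treatment_timepoints:
            if tp not in self.recovery_fraction:
                raise ConfigurationError(
                    f"recovery_fraction missing for timepoint {tp!r}")
            if not 0.0 <= self.recovery_fraction[tp] <= 1.0:
                raise ConfigurationError("recovery_fraction must be in [0, 1]")
        if self.hydration_parameter not in self.parameters:
            raise ConfigurationError(
                f"hydration parameter {self.hydration_parameter!r} missing")
        for p in self.response_parameters:
            if p not in self.parameters:
                raise ConfigurationError(f"response parameter {p!r} missing")
        if not 0 <= self.severity_loading < 1:
            raise ConfigurationError("severity_loading must be in [0, 1)")
        if not abs(self.baseline_correlation) < 1:
            raise ConfigurationError("|baseline_correlation| must be < 1")


# ---------------------------------------------------------------------------
# Object geometry
# ---------------------------------------------------------------------------

#: Lab-space unit directions of the rendered colour offset, per class.
_OFFSET_DIRECTIONS = {
    "wrinkle": np.array([-1.0, 0.0, 0.0]),          # pure shadowing
    "spot": np.array([-2.0, 1.0, 2.0]) / 3.0,       # darker, warmer
    "pore": np.array([-1.0, 0.0, 0.3]) / math.sqrt(1.09),
    "texture": np.array([-1.0, 0.0, 0.0]),
}


def default_object_params(object_class: str) -> dict:
    """Default sampling parameters per class.

    The defaults keep every nominal measurement at least 20% away from
    every classification threshold (thresholds at 3, 4 and 5 mm² carry
    ±20% bands jointly covering 2.4-6 mm², hence wrinkle areas above 6 mm²
    and pore/texture areas below 2.4 mm²), so objects generated in isolated
    mode are unambiguous class members.
    """
    if object_class == "wrinkle":
        return {"length_mm": (12.5, 14.0), "width_mm": 0.5,
                "contrast_delta_l": (6.0, 10.0), "curvature": (0.0, 0.04)}
    if object_class == "spot":
        return {"area_mm2": (6.5, 8.0), "delta_e": (3.8, 4.5),
                "eccentricity": (0.0, 0.45), "target_circularity": 27.0,
                "boundary_lobes": 5}
    if object_class == "pore":
        return {"area_mm2": (2.0, 2.4), "delta_e": (3.6, 4.4),
                "eccentricity": (0.0, 0.3), "target_circularity": 27.0,
                "boundary_lobes": 3}
    if object_class == "texture":
        return {"area_mm2": (1.8, 2.3), "delta_e": (3.6, 4.4),
                "aspect_ratio": (1.05, 1.4), "boundary_amplitude": 0.0}
    raise ConfigurationError(f"unknown object class {object_class!r}")


def _blob_curve(r0: float, amp: float, lobes: int, ar: float,
                n: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Continuous boundary curve of a modulated, area-preserving ellipse."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rad = r0 * (1.0 + amp * np.cos(lobes * theta))
    x = rad * np.cos(theta) * math.sqrt(ar)
    y = rad * np.sin(theta) / math.sqrt(ar)
    return x, y


def _curve_circularity(amp: float, lobes: int, ar: float) -> float:
    """perimeter²/area of the continuous blob boundary (scale-free)."""
    x, y = _blob_curve(1.0, amp, lobes, ar)
    dx = np.diff(np.r_[x, x[0]])
    dy = np.diff(np.r_[y, y[0]])
    perimeter = float(np.hypot(dx, dy).sum())
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return perimeter ** 2 / area


def solve_boundary_amplitude(target_circularity: float, lobes: int,
                             ar: float = 1.0) -> float:
    """Modulation amplitude giving a requested nominal circularity.

    Returns 0 if the smooth shape already meets or exceeds the target.
    """
    base = _curve_circularity(0.0, lobes, ar)
    if target_circularity <= base:
        return 0.0
    hi = 0.6  # star-convex (hence connected) for any amplitude < 1
    if _curve_circularity(hi, lobes, ar) < target_circularity:
        raise ConfigurationError(
            f"target circularity {target_circularity} not reachable with "
            f"{lobes} lobes at amplitude <= {hi}")
    return float(brentq(
        lambda a: _curve_circularity(a, lobes, ar) - target_circularity,
        0.0, hi, xtol=1e-6))


def _make_blob_mask(shape: tuple[int, int], center: tuple[float, float],
                    area_px: float, amp: float, lobes: int, ar: float,
                    orientation: float) -> np.ndarray:
    """Rasterize the modulated ellipse; pixel centres inside the curve."""
    r0 = math.sqrt(area_px / (math.pi * (1.0 + amp * amp / 2.0)))
    rmax = r0 * (1.0 + abs(amp)) * math.sqrt(max(ar, 1.0)) + 2.0
    cr, cc = center
    r_lo, r_hi = int(math.floor(cr - rmax)), int(math.ceil(cr + rmax)) + 1
    c_lo, c_hi = int(math.floor(cc - rmax)), int(math.ceil(cc + rmax)) + 1
    if r_lo < 0 or c_lo < 0 or r_hi > shape[0] or c_hi > shape[1]:
        raise DataError("blob does not fit inside the image at this centre")
    rr, cc_grid = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    u = (cc_grid - cc).astype(float)
    v = (rr - cr).astype(float)
    cosw, sinw = math.cos(orientation), math.sin(orientation)
    ul = u * cosw + v * sinw
    vl = -u * sinw + v * cosw
    up = ul / math.sqrt(ar)
    vp = vl * math.sqrt(ar)
    theta = np.arctan2(vp, up)
    inside = np.hypot(up, vp) <= r0 * (1.0 + amp * np.cos(lobes * theta))
    mask = np.zeros(shape, dtype=bool)
    mask[r_lo:r_hi, c_lo:c_hi] = inside
    return mask


def _arc_path_px(length_mm: float, curvature: float, center: tuple[float, float],
                 orientation: float, mm_per_px: float) -> np.ndarray:
    """Sampled points (row, col) of a circular-arc path of given arc length."""
    ds = 0.02  # mm
    n = max(int(round(length_mm / ds)) + 1, 2)
    s = np.linspace(0.0, length_mm, n)
    heading = orientation + curvature * s
    # integrate the unit tangent along arc length
    dx = np.cos(heading) * (length_mm / (n - 1))
    dy = np.sin(heading) * (length_mm / (n - 1))
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    x -= x.mean()
    y -= y.mean()
    pts = np.stack([y / mm_per_px + center[0],
                    x / mm_per_px + center[1]], axis=1)
    return pts


def _make_wrinkle_mask(shape: tuple[int, int], center: tuple[float, float],
                       length_mm: float, width_mm: float, curvature: float,
                       orientation: float, mm_per_px: float) -> np.ndarray:
    pts = _arc_path_px(length_mm, curvature, center, orientation, mm_per_px)
    half_w = 0.5 * width_mm / mm_per_px
    lo = pts.min(axis=0) - half_w
    hi = pts.max(axis=0) + half_w
    overflow = []
    if lo[0] < 0:
        overflow.append("top")
    if lo[1] < 0:
        overflow.append("left")
    if hi[0] > shape[0] - 1:
        overflow.append("bottom")
    if hi[1] > shape[1] - 1:
        overflow.append("right")
    if overflow:
        raise DataError(
            f"wrinkle path exits the image bounds at: {', '.join(overflow)}")
    r_lo, c_lo = np.floor(lo).astype(int)
    r_hi, c_hi = np.ceil(hi).astype(int) + 1
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    pix = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, _ = cKDTree(pts).query(pix, k=1)
    inside = (dist <= half_w).reshape(rr.shape)
    mask = np.zeros(shape, dtype=bool)
    mask[r_lo:r_hi, c_lo:c_hi] = inside
    return mask


# ---------------------------------------------------------------------------
# Planting on images
# ---------------------------------------------------------------------------

def plant_wrinkle(image: SkinImage, length_mm: float, width_mm: float,
                  contrast_delta_l: float, curvature: float,
                  rng: np.random.Generator,
                  center: tuple[float, float] | None = None,
                  orientation: float | None = None
                  ) -> tuple[SkinImage, PlantedObject]:
    """Render a constant-width dark curvilinear stroke.

    The path is a circular arc of the stated arc length (``curvature`` in
    1/mm; 0 gives a straight stroke). The recorded nominal length is the
    arc length; nominal area uses the stadium formula length*width + pi*w²/4.
    """
    if not width_mm < length_mm:
        raise DataError("width_mm must be smaller than length_mm")
    shape = image.shape
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    if orientation is None:
        orientation = float(rng.uniform(0.0, np.pi))
    mask = _make_wrinkle_mask(shape, center, length_mm, width_mm, curvature,
                              orientation, image.mm_per_px)
    lab = rgb_to_lab(image)
    lab[..., 0][mask] -= contrast_delta_l
    planted = PlantedObject(
        object_class="wrinkle",
        mask=mask,
        nominal_length_mm=length_mm,
        nominal_area_mm2=length_mm * width_mm + math.pi * width_mm ** 2 / 4.0,
        nominal_delta_e=abs(contrast_delta_l),
        nominal_circularity=(2.0 * length_mm + math.pi * width_mm) ** 2
        / (length_mm * width_mm + math.pi * width_mm ** 2 / 4.0),
        nominal_aspect_ratio=length_mm / width_mm,
        center=tuple(np.argwhere(mask).mean(axis=0)),
    )
    return SkinImage(lab_to_rgb(lab), image.mm_per_px, image.roi), planted


def plant_blob(image: SkinImage, object_class: str, area_mm2: float,
               delta_e: float, eccentricity: float,
               rng: np.random.Generator,
               center: tuple[float, float] | None = None,
               orientation: float | None = None,
               boundary_amplitude: float = 0.0,
               boundary_lobes: int = 6,
               target_circularity: float | None = None
               ) -> tuple[SkinImage, PlantedObject]:
    """Render an elliptical blob of a stated area and surround ΔE.

    ``eccentricity`` sets the axis ratio of the underlying ellipse
    (AR = 1/sqrt(1-e²)); a sinusoidal boundary modulation
    (``boundary_amplitude`` or, equivalently, ``target_circularity``)
    produces the irregular outlines of hyperpigmented spots. The colour
    offset is constant inside the mask with CIE76 magnitude ``delta_e``, so
    the mean contrast against the pre-existing local background equals the
    request up to rendering noise.
    """
    if object_class not in ("spot", "texture", "pore"):
        raise DataError(f"plant_blob cannot render class {object_class!r}")
    if not area_mm2 > 0:
        raise DataError("area_mm2 must be positive")
    if not 0.0 <= eccentricity < 1.0:
        raise DataError("eccentricity must be in [0, 1)")
    area_px = area_mm2 / image.mm_per_px ** 2
    if area_px < 4.0:
        raise DataError(
            f"requested area {area_mm2} mm² is below 4 px² at "
            f"{image.mm_per_px} mm/px (sub-resolution object)")
    ar = 1.0 / math.sqrt(1.0 - eccentricity ** 2)
    amp = boundary_amplitude
    if target_circularity is not None:
        amp = solve_boundary_amplitude(target_circularity, boundary_lobes, ar)
    shape = image.shape
    if center is None:
        center = (shape[0] / 2.0, shape[1] / 2.0)
    if orientation is None:
        orientation = float(rng.uniform(0.0, np.pi))
    mask = _make_blob_mask(shape, center, area_px, amp, boundary_lobes, ar,
                           orientation)
    lab = rgb_to_lab(image)
    lab[mask] += _OFFSET_DIRECTIONS[object_class] * delta_e
    planted = PlantedObject(
        object_class=object_class,
        mask=mask,
        nominal_area_mm2=area_mm2,
        nominal_delta_e=delta_e,
        nominal_circularity=_curve_circularity(amp, boundary_lobes, ar),
        nominal_aspect_ratio=ar,
        center=center,
    )
    return SkinImage(lab_to_rgb(lab), image.mm_per_px, image.roi), planted


# ---------------------------------------------------------------------------
# Labelled image generation
# ---------------------------------------------------------------------------

def _sample(rng: np.random.Generator, value):
    if isinstance(value, (tuple, list)) and len(value) == 2:
        return float(rng.uniform(value[0], value[1]))
    return value


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def generate_labeled_image(spec: ImageSpec
                           ) -> tuple[SkinImage, list[PlantedObject]]:
    """Generate one synthetic image with its ground-truth object list.

    Deterministic under ``spec.seed``. In isolated mode, objects are placed
    by rejection sampling so that planted masks keep at least
    ``spec.min_separation_px`` of clearance (never less than 2 px); if a
    request cannot be placed within ``spec.max_attempts`` attempts a
    :class:`~skinaging.errors.PlacementError` reporting the number placed
    is raised.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.size_px
    lab = np.empty((rows, cols, 3), dtype=float)
    lab[...] = np.asarray(spec.background_lab, dtype=float)
    lab[..., 0] += rng.normal(0.0, spec.background_noise_sd, (rows, cols))

    margin_px = spec.margin_mm / spec.mm_per_px
    separation = max(2, int(spec.min_separation_px))
    forbidden = np.zeros((rows, cols), dtype=bool)
    planted: list[PlantedObject] = []
    total_requested = sum(r.count for r in spec.object_requests)

    for request in spec.object_requests:
        merged = {**default_object_params(request.object_class),
                  **request.params}
        for _ in range(request.count):
            ok = False
            for _attempt in range(spec.max_attempts):
                params = {k: _sample(rng, v) for k, v in merged.items()}
                center = (float(rng.uniform(margin_px, rows - 1 - margin_px)),
                          float(rng.uniform(margin_px, cols - 1 - margin_px)))
                orientation = float(rng.uniform(0.0, np.pi))
                try:
                    if request.object_class == "wrinkle":
                        mask = _make_wrinkle_mask(
                            (rows, cols), center, params["length_mm"],
                            params["width_mm"], params["curvature"],
                            orientation, spec.mm_per_px)
                        obj = PlantedObject(
                            object_class="wrinkle", mask=mask,
                            nominal_length_mm=params["length_mm"],
                            nominal_area_mm2=(
                                params["length_mm"] * params["width_mm"]
                                + math.pi * params["width_mm"] ** 2 / 4.0),
                            nominal_delta_e=abs(params["contrast_delta_l"]),
                            nominal_circularity=(
                                (2.0 * params["length_mm"]
                                 + math.pi * params["width_mm"]) ** 2
                                / (params["length_mm"] * params["width_mm"]
                                   + math.pi * params["width_mm"] ** 2 / 4.0)),
                            nominal_aspect_ratio=(params["length_mm"]
                                                  / params["width_mm"]),
                            center=center)
                        offset = (_OFFSET_DIRECTIONS["wrinkle"]
                                  * params["contrast_delta_l"])
                    else:
                        if "aspect_ratio" in params:
                            ar = float(params["aspect_ratio"])
                            ecc = math.sqrt(max(1.0 - 1.0 / ar ** 2, 0.0))
                        else:
                            ecc = float(params.get("eccentricity", 0.0))
                            ar = 1.0 / math.sqrt(1.0 - ecc ** 2)
                        lobes = int(params.get("boundary_lobes", 6))
                        if params.get("target_circularity") is not None:
                            amp = solve_boundary_amplitude(
                                float(params["target_circularity"]), lobes, ar)
                        else:
                            amp = float(params.get("boundary_amplitude", 0.0))
                        area_px = params["area_mm2"] / spec.mm_per_px ** 2
                        if area_px < 4.0:
                            raise DataError("sub-resolution object request")
                        mask = _make_blob_mask((rows, cols), center, area_px,
                                               amp, lobes, ar, orientation)
                        obj = PlantedObject(
                            object_class=request.object_class, mask=mask,
                            nominal_area_mm2=params["area_mm2"],
                            nominal_delta_e=params["delta_e"],
                            nominal_circularity=_curve_circularity(
                                amp, lobes, ar),
                            nominal_aspect_ratio=ar,
                            center=center)
                        offset = (_OFFSET_DIRECTIONS[request.object_class]
                                  * params["delta_e"])
                except DataError:
                    continue  # did not fit; resample
                if spec.isolated and (mask & forbidden).any():
                    continue
                lab[mask] += offset
                planted.append(obj)
                if spec.isolated:
                    forbidden |= ndimage.binary_dilation(
                        mask, structure=_disk(separation))
                ok = True
                break
            if not ok:
                raise PlacementError(placed=len(planted),
                                     requested=total_requested)

    image = SkinImage(lab_to_rgb(lab), spec.mm_per_px)
    return image, planted


# ---------------------------------------------------------------------------
# Ground-truth export
# ---------------------------------------------------------------------------

def write_image_outputs(out_dir: str | Path, image: SkinImage,
                        planted: list[PlantedObject],
                        bit_depth: int = 16) -> dict[str, Path]:
    """Write the image, an indexed-label raster and a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "png" if bit_depth == 8 else "tiff"
    image_path = out / f"image.{ext}"
    image.to_file(image_path, bit_depth=bit_depth)
    labels = np.zeros(image.shape, dtype=np.uint8)
    rows = []
    for i, obj in enumerate(planted, start=1):
        labels[obj.mask] = i
        rows.append({
            "label": i, "object_class": obj.object_class,
            "area_mm2": obj.nominal_area_mm2,
            "delta_e": obj.nominal_delta_e,
            "length_mm": obj.nominal_length_mm,
            "circularity": obj.nominal_circularity,
            "aspect_ratio": obj.nominal_aspect_ratio,
            "center_row": obj.center[0], "center_col": obj.center[1],
        })
    labels_path = out / "labels.png"
    iio.imwrite(labels_path, labels)
    manifest_path = out / "objects.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return {"image": image_path, "labels": labels_path,
            "manifest": manifest_path}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _solve_response_loading(r: float, beta_h: float, var_dh: float, t_h: float,
                            cov_hp: float, var_dp: float, w_p: float,
                            rho12: float, param: str) -> float:
    """Loading of one outcome on the shared response factor.

    Solves (A + beta_h*b)² = r²·S²·(Q + b²) with A = rho12²·cov_hp,
    S² = rho12²·var_dh + t_h, Q = rho12²·var_dp + w_p², picking the root
    that gives the requested correlation its sign.
    """
    a_term = rho12 ** 2 * cov_hp
    s2 = rho12 ** 2 * var_dh + t_h
    q = rho12 ** 2 * var_dp + w_p ** 2
    if beta_h == 0.0:
        if r == 0.0 and a_term == 0.0:
            return 0.0
        raise ConfigurationError(
            f"response correlation target {r} is not achievable for "
            f"parameter {param!r}: hydration has no response loading")
    if r == 0.0:
        return -a_term / beta_h
    a2 = beta_h ** 2 - r * r * s2
    a1 = 2.0 * a_term * beta_h
    a0 = a_term * a_term - r * r * s2 * q
    if abs(a2) < 1e-12:
        if a1 == 0.0:
            raise ConfigurationError(
                f"response correlation target {r} is not achievable for "
                f"parameter {param!r}")
        roots = [-a0 / a1]
    else:
        disc = a1 * a1 - 4.0 * a2 * a0
        if disc < 0.0:
            raise ConfigurationError(
                f"response correlation target {r} is not achievable for "
                f"parameter {param!r} (implied correlation structure is "
                "not positive definite)")
        sq = math.sqrt(disc)
        roots = [(-a1 - sq) / (2.0 * a2), (-a1 + sq) / (2.0 * a2)]
    valid = [b for b in roots
             if (a_term + beta_h * b) * r > 0.0]
    if not valid:
        raise ConfigurationError(
            f"response correlation target {r} is not achievable for "
            f"parameter {param!r} (no sign-consistent factor loading)")
    return min(valid, key=abs)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a longitudinal cohort as a tidy table.

    Returns one row per (subject_id, timepoint, parameter) with columns
    ``subject_id, timepoint, parameter, value``. Deterministic under
    ``spec.seed``. See the module docstring for the generative model.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.parameters)
    n = spec.n_subjects
    rho_b = spec.baseline_correlation
    g = spec.severity_loading

    severity = rng.standard_normal(n)
    response = rng.standard_normal(n)
    x = {p: rng.standard_normal(n) for p in names}
    eta = {p: rng.standard_normal(n) for p in names}

    v99, v0, reversion, sd_d, direction = {}, {}, {}, {}, {}
    for p in names:
        m99, s99, m0, s0 = spec.parameters[p]
        d = 1.0 if m0 >= m99 else -1.0
        c = g * d
        y = (rho_b * x[p]
             + math.sqrt(1.0 - rho_b ** 2)
             * (c * severity + math.sqrt(1.0 - c * c) * eta[p]))
        v99[p] = m99 + s99 * x[p]
        v0[p] = m0 + s0 * y
        reversion[p] = v99[p] - v0[p]
        sd_d[p] = math.sqrt(s99 ** 2 + s0 ** 2 - 2.0 * rho_b * s99 * s0)
        direction[p] = d

    treat = spec.treatment_timepoints
    beta = {p: 0.0 for p in names}
    noise_w = {p: spec.outcome_noise_frac * sd_d[p] for p in names}
    if treat:
        rho12 = spec.recovery_fraction[treat[-1]]
        hyd = spec.hydration_parameter
        t_h = (spec.hydration_response_sd_frac * sd_d[hyd]) ** 2
        beta[hyd] = spec.hydration_response_share * math.sqrt(t_h)
        noise_w[hyd] = math.sqrt(max(t_h - beta[hyd] ** 2, 0.0))
        _, _, _, s0_h = spec.parameters[hyd]
        if t_h > 0.0:  # degenerate noise-free limit: no response factor
            for p in spec.response_parameters:
                if p == hyd:
                    continue
                _, _, _, s0_p = spec.parameters[p]
                cov_hp = (s0_h * s0_p * (1.0 - rho_b ** 2)
                          * (g * direction[hyd]) * (g * direction[p]))
                beta[p] = _solve_response_loading(
                    spec.response_correlation, beta[hyd], sd_d[hyd] ** 2, t_h,
                    cov_hp, sd_d[p] ** 2, noise_w[p], rho12, p)

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    frames = []
    for p in names:
        frames.append(pd.DataFrame({
            "subject_id": subject_ids,
            "timepoint": spec.baseline_timepoint,
            "parameter": p, "value": v99[p]}))
        frames.append(pd.DataFrame({
            "subject_id": subject_ids,
            "timepoint": spec.pretreat_timepoint,
            "parameter": p, "value": v0[p]}))
    for tp in treat:
        rho_t = spec.recovery_fraction[tp]
        scale = rho_t / rho12 if rho12 > 0 else 1.0
        for p in names:
            eps = rng.standard_normal(n)
            value = (v0[p] + rho_t * reversion[p]
                     + scale * (beta[p] * response + noise_w[p] * eps))
            frames.append(pd.DataFrame({
                "subject_id": subject_ids, "timepoint": tp,
                "parameter": p, "value": value}))
    tidy = pd.concat(frames, ignore_index=True)
    return tidy
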