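"""End-to-end orchestration: image -> fractions -> scores -> reversal -> stats.

A single :class:`RunConfig` carries every numeric constant of the analysis
(the printed classification thresholds are its defaults), serialises
losslessly to YAML, and stamps each run with a manifest (config hash, input
hash, package version) so outputs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import polygon2mask

from . import __version__
from .classification_scoring import (AgingScoreScaler, SkinObjectClassifier,
                                     area_fractions, reversal_years)
from .cohort_stats import change_correlation, summary_table
from .color_metrics import rgb_to_lab, roi_color_summary
from .errors import (ConfigurationError, DataError, PipelineStageError,
                     UndefinedReversalError)
from .object_extraction import (SegmentationParams, measure_all_objects,
                                segment_candidates)
from .types import FeatureFractions, SkinImage

logger = logging.getLogger("skinaging")

__all__ = ["RunConfig", "ImageResult", "CohortResult",
           "run_image_pipeline", "run_cohort_pipeline"]

#: Colour-coded overlay palette per class (RGB, 0-1).
_OVERLAY_COLORS = {
    "wrinkle": (0.0, 0.4, 1.0),
    "spot": (0.8, 0.2, 0.0),
    "pore": (1.0, 0.8, 0.0),
    "texture": (0.0, 0.8, 0.2),
    "none": (0.6, 0.6, 0.6),
}


@dataclass
class RunConfig:
    """Every tunable constant of the analysis, in one serialisable record.

    The classification thresholds default to the printed rule constants:
    wrinkle (5 mm, 2.5, 34), spot (5 mm², 3, 20), texture (3 mm²,
    [0.5, 2], 1.5), pore (4 mm², 2, 20).
    """

    mm_per_px: float = 0.1
    roi_polygon: list[tuple[float, float]] | None = None  # (row, col), 0-based
    smoothing_scale_mm: float = 10.0
    candidate_delta_e: float = 1.5
    ring_width_mm: float = 1.0
    perimeter_scheme: str = "corrected"
    thresholds: dict = field(default_factory=dict)  # SkinObjectClassifier kwargs
    pore_multiplier: float = 3.0
    exclude_border_objects: bool = True
    scaling_bounds: dict | None = None  # parameter -> (min, max), from a prior fit
    score_columns: tuple[str, str, str] = ("wrinkles", "spots", "roughness")
    baseline_timepoint: str = "1999"
    pretreat_timepoint: str = "0M"
    interval_years: float = 11.0
    seed: int = 0

    def classifier(self) -> SkinObjectClassifier:
        return SkinObjectClassifier(**self.thresholds).fit()

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(smoothing_scale_mm=self.smoothing_scale_mm,
                                  candidate_delta_e=self.candidate_delta_e)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["score_columns"] = list(self.score_columns)
        if self.roi_polygon is not None:
            d["roi_polygon"] = [list(v) for v in self.roi_polygon]
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        if "score_columns" in data:
            data["score_columns"] = tuple(data["score_columns"])
        if data.get("roi_polygon") is not None:
            data["roi_polygon"] = [tuple(v) for v in data["roi_polygon"]]
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"invalid YAML config: {exc}") from exc
        return cls.from_dict(data)

    def validate(self) -> None:
        if not self.mm_per_px > 0:
            raise ConfigurationError("mm_per_px must be positive")
        self.segmentation_params().validate()
        try:
            self.classifier()
        except TypeError as exc:
            raise ConfigurationError(f"bad threshold name: {exc}") from exc

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class ImageResult:
    fractions: FeatureFractions
    objects: pd.DataFrame
    labels: np.ndarray
    overlay: np.ndarray  # float RGB


@dataclass
class CohortResult:
    scores: pd.DataFrame
    scaling_bounds: dict
    reversal: pd.DataFrame
    reversal_summary: pd.DataFrame
    stats: pd.DataFrame
    excluded_subjects: int = 0


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            return False
    return _Ctx()


def _roi_mask(config: RunConfig, shape: tuple[int, int]) -> np.ndarray:
    if config.roi_polygon is None:
        return np.ones(shape, dtype=bool)
    mask = polygon2mask(shape, np.asarray(config.roi_polygon, dtype=float))
    if not mask.any():
        raise DataError("ROI polygon covers no pixels")
    return mask


def _render_overlay(image: SkinImage, labels: np.ndarray,
                    objects: pd.DataFrame) -> np.ndarray:
    overlay = np.clip(image.rgb.copy(), 0.0, 1.0)
    class_of = dict(zip(objects.get("label", []), objects.get("object_class", [])))
    for oid, cls in class_of.items():
        mask = labels == oid
        color = np.asarray(_OVERLAY_COLORS.get(cls, _OVERLAY_COLORS["none"]))
        overlay[mask] = 0.45 * overlay[mask] + 0.55 * color
    return overlay


def run_image_pipeline(config: RunConfig,
                       image: SkinImage | str | Path,
                       out_dir: str | Path | None = None) -> ImageResult:
    """Analyse one image: segment, measure, classify, aggregate fractions.

    When ``out_dir`` is given, writes ``objects.csv``, ``fractions.csv``,
    ``labels.png``, ``overlay.png`` and ``manifest.yaml``. Identical config
    and input produce bit-identical CSV outputs.
    """
    config.validate()
    input_name = None
    if not isinstance(image, SkinImage):
        input_name = str(image)
        with _stage("load_image"):
            image = SkinImage.from_file(image, mm_per_px=config.mm_per_px)
    roi = image.roi if image.roi is not None else _roi_mask(config, image.shape)

    with _stage("rgb_to_lab"):
        lab = rgb_to_lab(image)
    with _stage("segment_candidates"):
        seg = segment_candidates(lab, roi, config.segmentation_params(),
                                 image.mm_per_px)
    with _stage("measure_object"):
        measurements = measure_all_objects(
            seg, lab, image.mm_per_px, ring_width_mm=config.ring_width_mm,
            perimeter_scheme=config.perimeter_scheme)
        objects = pd.DataFrame([m.as_dict() for m in measurements])
    with _stage("classify_object"):
        if len(objects):
            objects["object_class"] = config.classifier().predict(objects)
        else:
            objects = objects.reindex(columns=[
                "label", "area_px", "area_mm2", "perimeter_px", "length_mm",
                "aspect_ratio", "circularity", "surround_delta_e",
                "perimeter_length_ratio", "degenerate", "touches_border",
                "object_class"])
    with _stage("area_fractions"):
        color = roi_color_summary(lab, roi)
        fractions = area_fractions(
            objects, int(roi.sum()), color,
            pore_multiplier=config.pore_multiplier,
            exclude_border=config.exclude_border_objects)

    counts = (objects["object_class"].value_counts().to_dict()
              if len(objects) else {})
    logger.info("image analysed: %d objects (%s)", len(objects),
                ", ".join(f"{k}={v}" for k, v in sorted(counts.items()))
                or "none")

    overlay = _render_overlay(image, seg.labels, objects)
    result = ImageResult(fractions=fractions, objects=objects,
                         labels=seg.labels, overlay=overlay)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        objects.to_csv(out / "objects.csv", index=False)
        pd.DataFrame([fractions.as_dict()]).to_csv(
            out / "fractions.csv", index=False)
        iio.imwrite(out / "labels.png",
                    seg.labels.astype(np.uint16 if seg.labels.max() > 255
                                      else np.uint8))
        iio.imwrite(out / "overlay.png",
                    (np.clip(overlay, 0, 1) * 255 + 0.5).astype(np.uint8))
        manifest = {
            "config_hash": config.config_hash(),
            "input": input_name,
            "input_hash": hashlib.sha256(
                np.ascontiguousarray(image.rgb).tobytes()).hexdigest()[:16],
            "version": __version__,
            "n_objects": int(len(objects)),
            "class_counts": {str(k): int(v) for k, v in counts.items()},
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return result


def run_cohort_pipeline(config: RunConfig, fractions: pd.DataFrame,
                        out_dir: str | Path | None = None) -> CohortResult:
    """Score a cohort of per-image fractions and estimate reversal years.

    ``fractions`` is a tidy table (subject_id, timepoint, parameter, value)
    carrying at least the three scored parameters at the baseline and
    pre-treatment timepoints. Subjects lacking either anchor timepoint are
    excluded from the reversal estimate with a logged count.
    """
    config.validate()
    for col in ("subject_id", "timepoint", "parameter", "value"):
        if col not in fractions.columns:
            raise DataError(f"cohort table lacks column {col!r}")

    cols = config.score_columns
    with _stage("fit_scale_scores"):
        wide = fractions[fractions["parameter"].isin(cols)].pivot_table(
            index=["subject_id", "timepoint"], columns="parameter",
            values="value", aggfunc="first").reset_index()
        if any(c not in wide.columns for c in cols):
            raise DataError(f"cohort table lacks scored parameters {cols}")
        scaler = AgingScoreScaler(columns=cols)
        if config.scaling_bounds is not None:
            scaler.data_min_ = pd.Series(
                {c: float(config.scaling_bounds[c][0]) for c in cols})
            scaler.data_max_ = pd.Series(
                {c: float(config.scaling_bounds[c][1]) for c in cols})
        else:
            scaler.fit(wide)
        scores = pd.concat(
            [wide[["subject_id", "timepoint"]], scaler.transform(wide)],
            axis=1)

    with _stage("reversal_years"):
        overall = scores.pivot(index="subject_id", columns="timepoint",
                               values="overall")
        base, pre = config.baseline_timepoint, config.pretreat_timepoint
        for tp in (base, pre):
            if tp not in overall.columns:
                raise DataError(f"anchor timepoint {tp!r} absent from cohort")
        treat_tps = [t for t in overall.columns if t not in (base, pre)]
        complete = overall[[base, pre]].dropna()
        excluded = len(overall) - len(complete)
        if excluded:
            logger.warning("%d subject(s) lack both anchor timepoints; "
                           "excluded from reversal", excluded)
        rows = []
        for sid, anchors in complete.iterrows():
            for tp in treat_tps:
                score_t = overall.at[sid, tp]
                if pd.isna(score_t):
                    continue
                try:
                    est = reversal_years(score_t, anchors[pre], anchors[base],
                                         interval_years=config.interval_years)
                except UndefinedReversalError:
                    logger.warning("subject %s: reversal undefined "
                                   "(no aging between anchors)", sid)
                    continue
                rows.append({"subject_id": sid, "timepoint": tp,
                             "years": est.years,
                             "numerator_delta": est.numerator_delta,
                             "denominator_delta": est.denominator_delta})
        reversal = pd.DataFrame(
            rows, columns=["subject_id", "timepoint", "years",
                           "numerator_delta", "denominator_delta"])
        if len(reversal):
            summary = (reversal.groupby("timepoint")["years"]
                       .agg(mean_years="mean", sd_years="std", n="count")
                       .reindex(treat_tps).dropna(how="all").reset_index())
        else:
            summary = pd.DataFrame(
                columns=["timepoint", "mean_years", "sd_years", "n"])

    with _stage("cohort_stats"):
        stats = summary_table(fractions,
                              baseline=base, pretreat=pre)

    result = CohortResult(scores=scores, scaling_bounds=scaler.bounds(),
                          reversal=reversal, reversal_summary=summary,
                          stats=stats, excluded_subjects=excluded)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores.to_csv(out / "scores.csv", index=False)
        reversal.to_csv(out / "reversal.csv", index=False)
        summary.to_csv(out / "reversal_summary.csv", index=False)
        stats.to_csv(out / "summary_stats.csv", index=False)
        (out / "manifest.yaml").write_text(yaml.safe_dump({
            "config_hash": config.config_hash(),
            "version": __version__,
            "scaling_bounds": {k: list(v)
                               for k, v in scaler.bounds().items()},
            "excluded_subjects": int(excluded),
        }))
    return result


def cohort_change_correlations(fractions: pd.DataFrame,
                               anchor: str = "0M", endpoint: str = "12M",
                               against: str = "hydration",
                               parameters: tuple[str, ...] = (
                                   "tewl", "wrinkles", "spots", "roughness")
                               ) -> pd.DataFrame:
    """Pearson r between the change of one parameter and each of the others.

    Mirrors the treatment-response analysis: change of hydration
    (endpoint − anchor) against the change of each outcome parameter.
    """
    rows = []
    for p in parameters:
        r, pval, n = change_correlation(fractions, against, p, anchor, endpoint)
        rows.append({"parameter_a": against, "parameter_b": p,
                     "r": r, "p": pval, "n": n})
    return pd.DataFrame(rows)
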