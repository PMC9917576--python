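"""Rule-based object classification, area fractions, aging score, reversal years.

The four object classes are decided by fixed geometric and colour-contrast
rules, tested in precedence order wrinkle -> spot -> pore -> texture (most to
least specific; the ordering also resolves the printed pore/texture overlap
in favour of the stricter class). Thresholds are inclusive: an object exactly
at a printed boundary is a class member.

Default thresholds (all overridable):

============  =======================================================
wrinkle       length >= 5 mm, perimeter/length <= 2.5, circularity >= 34
spot          area >= 5 mm^2, surround dE >= 3, circularity >= 20
pore          area <= 4 mm^2, surround dE >= 2, circularity >= 20
texture       area <= 3 mm^2, aspect ratio in [0.5, 2], surround dE >= 1.5
============  =======================================================

Scoring: wrinkle, spot and roughness (texture) fractions are min-max scaled
to [0, 1] over the pooled analysed table, and the Overall Skin Aging Score is
their per-observation sum (range 0-3). Reversal years place a follow-up score
on the affine axis anchored at 0 (pre-treatment) and -interval_years (the
decade-earlier baseline).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, UndefinedReversalError
from .types import (UNCLASSIFIED, ColorSummary, FeatureFractions,
                    ObjectMeasurements, ReversalEstimate)

__all__ = ["SkinObjectClassifier", "classify_object", "area_fractions",
           "AgingScoreScaler", "fit_scale_scores", "reversal_years"]

#: Measurement columns the classifier consumes.
_FEATURES = ("length_mm", "area_mm2", "aspect_ratio", "circularity",
             "surround_delta_e", "perimeter_length_ratio")


class SkinObjectClassifier(ClassifierMixin, BaseEstimator):
    """Deterministic rule-based classifier for measured skin objects.

    A scikit-learn compatible estimator whose parameters are the class
    thresholds; ``fit`` only validates (there is nothing to learn) so the
    classifier composes with pipelines and ``clone``.

    ``predict`` accepts a DataFrame (or list of dicts /
    :class:`~skinaging.types.ObjectMeasurements`) carrying the measurement
    columns and returns one of ``{"wrinkle", "spot", "pore", "texture",
    "none"}`` per row.
    """

    def __init__(self,
                 wrinkle_min_length_mm: float = 5.0,
                 wrinkle_max_perimeter_length_ratio: float = 2.5,
                 wrinkle_min_circularity: float = 34.0,
                 spot_min_area_mm2: float = 5.0,
                 spot_min_delta_e: float = 3.0,
                 spot_min_circularity: float = 20.0,
                 pore_max_area_mm2: float = 4.0,
                 pore_min_delta_e: float = 2.0,
                 pore_min_circularity: float = 20.0,
                 texture_max_area_mm2: float = 3.0,
                 texture_min_aspect_ratio: float = 0.5,
                 texture_max_aspect_ratio: float = 2.0,
                 texture_min_delta_e: float = 1.5):
        self.wrinkle_min_length_mm = wrinkle_min_length_mm
        self.wrinkle_max_perimeter_length_ratio = wrinkle_max_perimeter_length_ratio
        self.wrinkle_min_circularity = wrinkle_min_circularity
        self.spot_min_area_mm2 = spot_min_area_mm2
        self.spot_min_delta_e = spot_min_delta_e
        self.spot_min_circularity = spot_min_circularity
        self.pore_max_area_mm2 = pore_max_area_mm2
        self.pore_min_delta_e = pore_min_delta_e
        self.pore_min_circularity = pore_min_circularity
        self.texture_max_area_mm2 = texture_max_area_mm2
        self.texture_min_aspect_ratio = texture_min_aspect_ratio
        self.texture_max_aspect_ratio = texture_max_aspect_ratio
        self.texture_min_delta_e = texture_min_delta_e

    # -- sklearn API -------------------------------------------------------

    def fit(self, X=None, y=None):
        """No-op fit (rules are fixed); validates thresholds."""
        for name, value in self.get_params().items():
            if not np.isfinite(value):
                raise DataError(f"threshold {name} must be finite, got {value}")
        self.classes_ = np.array(["none", "pore", "spot", "texture", "wrinkle"])
        return self

    def rule_masks(self, X: pd.DataFrame) -> pd.DataFrame:
        """Boolean rule-set outcome per class, before precedence.

        Exposed so the precedence decision can be audited; classification
        takes the first firing rule in the order wrinkle, spot, pore,
        texture.
        """
        df = _as_frame(X)
        wrinkle = ((df["length_mm"] >= self.wrinkle_min_length_mm)
                   & (df["perimeter_length_ratio"]
                      <= self.wrinkle_max_perimeter_length_ratio)
                   & (df["circularity"] >= self.wrinkle_min_circularity))
        spot = ((df["area_mm2"] >= self.spot_min_area_mm2)
                & (df["surround_delta_e"] >= self.spot_min_delta_e)
                & (df["circularity"] >= self.spot_min_circularity))
        pore = ((df["area_mm2"] <= self.pore_max_area_mm2)
                & (df["surround_delta_e"] >= self.pore_min_delta_e)
                & (df["circularity"] >= self.pore_min_circularity))
        texture = ((df["area_mm2"] <= self.texture_max_area_mm2)
                   & (df["aspect_ratio"] >= self.texture_min_aspect_ratio)
                   & (df["aspect_ratio"] <= self.texture_max_aspect_ratio)
                   & (df["surround_delta_e"] >= self.texture_min_delta_e))
        return pd.DataFrame({"wrinkle": wrinkle, "spot": spot,
                             "pore": pore, "texture": texture},
                            index=df.index)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        df = _as_frame(X)
        if not np.isfinite(df[list(_FEATURES)].to_numpy()).all():
            raise DataError("measurement fields must be finite")
        masks = self.rule_masks(df)
        out = np.full(len(df), UNCLASSIFIED, dtype=object)
        undecided = np.ones(len(df), dtype=bool)
        for cls in ("wrinkle", "spot", "pore", "texture"):  # precedence
            fire = masks[cls].to_numpy() & undecided
            out[fire] = cls
            undecided &= ~fire
        return out.astype(str)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    if isinstance(X, ObjectMeasurements):
        return pd.DataFrame([X.as_dict()])
    if isinstance(X, dict):
        return pd.DataFrame([X])
    if isinstance(X, Iterable):
        rows = [x.as_dict() if isinstance(x, ObjectMeasurements) else dict(x)
                for x in X]
        return pd.DataFrame(rows)
    raise DataError(f"cannot interpret {type(X).__name__} as measurements")


def classify_object(m, **threshold_overrides) -> str:
    """Classify one measured object; thin wrapper over the estimator."""
    clf = SkinObjectClassifier(**threshold_overrides).fit()
    return str(clf.predict(_as_frame(m))[0])


def area_fractions(objects: pd.DataFrame | list, roi_px: int,
                   color: ColorSummary,
                   pore_multiplier: float = 3.0,
                   exclude_border: bool = True) -> FeatureFractions:
    """Per-class area fractions over the ROI, plus the ROI colour summary.

    Each fraction is the summed pixel area of that class divided by the ROI
    pixel count; the pore fraction additionally carries the conventional x3
    multiplier. Border-touching objects are excluded by default (their
    shapes are clipped).
    """
    if not roi_px > 0:
        raise DataError("roi_px must be positive")
    df = _as_frame(objects) if not isinstance(objects, pd.DataFrame) else objects
    totals = {cls: 0.0 for cls in ("wrinkle", "spot", "texture", "pore")}
    if len(df):
        if "object_class" not in df.columns or "area_px" not in df.columns:
            raise DataError("objects must carry 'object_class' and 'area_px'")
        sel = df
        if exclude_border and "touches_border" in df.columns:
            sel = df[~df["touches_border"].astype(bool)]
        sums = sel.groupby("object_class")["area_px"].sum()
        for cls in totals:
            totals[cls] = float(sums.get(cls, 0.0))
    return FeatureFractions(
        wrinkle_fraction=totals["wrinkle"] / roi_px,
        spot_fraction=totals["spot"] / roi_px,
        texture_fraction=totals["texture"] / roi_px,
        pore_fraction=totals["pore"] / roi_px * pore_multiplier,
        lightness=color.lightness,
        redness=color.redness,
        yellowness=color.yellowness,
    )


class AgingScoreScaler(TransformerMixin, BaseEstimator):
    """Pooled min-max scaling of wrinkle/spot/roughness to [0, 1].

    ``fit`` learns, per parameter, the minimum and maximum over all pooled
    subject x timepoint observations (``data_min_``, ``data_max_``);
    ``transform`` returns the scaled values plus their per-observation sum,
    the Overall Skin Aging Score (range 0-3). The learned bounds are fitted
    attributes so they can be reused on new data.
    """

    def __init__(self, columns: tuple[str, str, str] =
                 ("wrinkles", "spots", "roughness")):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        df = X
        missing = [c for c in self.columns if c not in df.columns]
        if missing:
            raise DataError(f"missing scoring columns: {missing}")
        mins, maxs = {}, {}
        for c in self.columns:
            vals = pd.to_numeric(df[c], errors="coerce").dropna()
            if vals.nunique() < 2:
                raise DataError(
                    f"parameter '{c}' is constant over the pooled table; "
                    "min-max scaling undefined")
            mins[c] = float(vals.min())
            maxs[c] = float(vals.max())
        self.data_min_ = pd.Series(mins)
        self.data_max_ = pd.Series(maxs)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self)
        out = {}
        for c in self.columns:
            lo, hi = self.data_min_[c], self.data_max_[c]
            out[f"scaled_{c}"] = (pd.to_numeric(X[c]) - lo) / (hi - lo)
        scores = pd.DataFrame(out, index=X.index)
        scores["overall"] = scores.sum(axis=1)
        return scores

    def bounds(self) -> dict[str, tuple[float, float]]:
        check_is_fitted(self)
        return {c: (float(self.data_min_[c]), float(self.data_max_[c]))
                for c in self.columns}


def fit_scale_scores(cohort_fractions: pd.DataFrame,
                     columns: tuple[str, str, str] =
                     ("wrinkles", "spots", "roughness")
                     ) -> tuple[pd.DataFrame, dict]:
    """Min-max scale the three aging parameters and sum them.

    Returns ``(scores, bounds)`` where ``scores`` carries scaled_* columns
    and ``overall``, and ``bounds`` maps each parameter to its pooled
    (min, max) for reuse on new data.
    """
    scaler = AgingScoreScaler(columns=columns).fit(cohort_fractions)
    return scaler.transform(cohort_fractions), scaler.bounds()


def reversal_years(score_t: float, score_0m: float, score_1999: float,
                   interval_years: float = 11.0,
                   eps: float = 1e-6) -> ReversalEstimate:
    """Reversal years of skin aging from three Overall Skin Aging Scores.

    years = interval_years * (score_t - score_0m) / (score_0m - score_1999)

    so a score unchanged from pre-treatment maps to 0 and a score fully
    returned to the decade-earlier baseline maps to -interval_years.
    Affine-invariant: a common affine transform of all three scores leaves
    the result unchanged.
    """
    numerator = float(score_t) - float(score_0m)
    denominator = float(score_0m) - float(score_1999)
    if abs(denominator) < eps:
        raise UndefinedReversalError(
            "pre-treatment score equals the decade-earlier baseline within "
            f"epsilon ({eps}); the subject did not age on this score")
    return ReversalEstimate(years=interval_years * numerator / denominator,
                            numerator_delta=numerator,
                            denominator_delta=denominator)
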