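"""Shape descriptors and candidate segmentation.

Perimeter and skeleton length are checked against independent brute-force
oracles on small enumerable masks, and against closed forms for digital
disks, rectangles and ellipses.
"""

import math

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import floyd_warshall
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk, skeletonize

from skinaging import (ConfigurationError, DataError, ImageSpec,
                       ObjectRequest, SegmentationParams,
                       generate_labeled_image, measure_object, rgb_to_lab,
                       segment_candidates)
from skinaging.object_extraction import (boundary_perimeter,
                                         skeleton_length_px)

from conftest import match_planted_to_detected


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def chain_perimeter_star_convex(mask):
    """Brute-force chain perimeter: order boundary pixels by angle.

    Valid for star-convex masks (disks, ellipses): boundary pixels sorted
    around the centroid form the boundary cycle, and each consecutive step
    weighs 1 (edge) or sqrt(2) (diagonal). Independent of the Moore trace.
    """
    from scipy.ndimage import binary_erosion
    boundary = mask & ~binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    centroid = np.argwhere(mask).mean(axis=0)
    ang = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    pts = pts[np.argsort(ang)]
    total = 0.0
    for a, b in zip(pts, np.roll(pts, -1, axis=0)):
        d = np.abs(a - b)
        total += math.sqrt(2.0) if (d[0] == 1 and d[1] == 1) else np.abs(d).sum()
    return total


def longest_geodesic_all_pairs(mask):
    """Brute-force skeleton length: all-pairs shortest paths, take the max."""
    skel = skeletonize(mask)
    pts = [tuple(p) for p in np.argwhere(skel)]
    if len(pts) <= 1:
        return 1.0 if mask.any() else 0.0
    idx = {p: i for i, p in enumerate(pts)}
    rows, cols, w = [], [], []
    for (r, c) in pts:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    rows.append(idx[(r, c)])
                    cols.append(j)
                    w.append(math.sqrt(2.0) if dr and dc else 1.0)
    g = coo_matrix((w, (rows, cols)), shape=(len(pts), len(pts))).tocsr()
    dist = floyd_warshall(g, directed=False)
    dist[~np.isfinite(dist)] = 0.0
    return dist.max() + 1.0


# ---------------------------------------------------------------------------
# perimeter
# ---------------------------------------------------------------------------

class TestBoundaryPerimeter:
    @pytest.mark.parametrize("h,w", [(5, 100), (1, 10), (7, 7), (2, 3)])
    def test_rectangle_chain_closed_form(self, h, w):
        # axis-aligned rectangle: all boundary steps are edge steps
        mask = np.ones((h, w), dtype=bool)
        expected = 2.0 * (h - 1) + 2.0 * (w - 1) if min(h, w) > 1 \
            else 2.0 * (max(h, w) - 1)
        assert boundary_perimeter(mask, "chain") == pytest.approx(expected)

    @pytest.mark.parametrize("radius", [6, 11, 17])
    def test_star_convex_oracle_agreement(self, radius):
        mask = np.pad(disk(radius), 1)
        got = boundary_perimeter(mask, "chain")
        oracle = chain_perimeter_star_convex(mask)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_single_pixel(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert boundary_perimeter(mask) == 4.0

    def test_corrected_below_chain_on_disk(self):
        mask = np.pad(disk(20), 1)
        assert boundary_perimeter(mask, "corrected") < \
            boundary_perimeter(mask, "chain")

    def test_unknown_scheme(self):
        with pytest.raises(ConfigurationError):
            boundary_perimeter(np.ones((3, 3), bool), "bogus")


class TestSkeletonLength:
    def test_straight_line(self):
        mask = np.zeros((5, 30), dtype=bool)
        mask[2, 2:22] = True  # 20 px line
        assert skeleton_length_px(mask) == pytest.approx(20.0)

    def test_diagonal_line(self):
        mask = np.eye(15, dtype=bool)
        assert skeleton_length_px(mask) == pytest.approx(14 * math.sqrt(2) + 1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((24, 24), dtype=bool)
        r, c = 12, 12
        for _ in range(60):  # random walk blob: irregular small mask
            mask[r, c] = True
            r = int(np.clip(r + rng.integers(-1, 2), 1, 22))
            c = int(np.clip(c + rng.integers(-1, 2), 1, 22))
        got = skeleton_length_px(mask)
        assert got == pytest.approx(longest_geodesic_all_pairs(mask))


# ---------------------------------------------------------------------------
# measure_object closed forms
# ---------------------------------------------------------------------------

def _measure_mask(mask, mm_per_px=0.1, **kw):
    lab = np.empty(mask.shape + (3,))
    lab[...] = (60.0, 13.0, 20.0)
    lab[mask, 0] -= 8.0
    labels = mask.astype(int)
    return measure_object(labels, 1, lab, mm_per_px, **kw)


class TestMeasureObject:
    def test_disk_circularity_isoperimetric(self):
        m = _measure_mask(np.pad(disk(30), 2))
        assert m.circularity == pytest.approx(4 * math.pi, rel=0.10)
        assert m.aspect_ratio == pytest.approx(1.0, abs=0.05)

    def test_thin_stroke_geometry(self):
        mask = np.zeros((40, 140), dtype=bool)
        mask[18:23, 20:120] = True  # 10 mm x 0.5 mm at 0.1 mm/px
        m = _measure_mask(mask)
        assert m.length_mm == pytest.approx(10.0, rel=0.10)
        assert 1.8 <= m.perimeter_length_ratio <= 2.5
        assert m.area_mm2 == pytest.approx(5.0, rel=0.01)

    def test_ellipse_aspect_ratio(self):
        mask = np.zeros((120, 220), dtype=bool)
        rr, cc = draw_ellipse(60, 110, 20, 80)
        mask[rr, cc] = True
        m = _measure_mask(mask)
        assert m.aspect_ratio == pytest.approx(4.0, rel=0.10)

    def test_rotation_robustness(self):
        base = np.zeros((160, 160), dtype=bool)
        rr, cc = draw_ellipse(80, 80, 15, 45)
        base[rr, cc] = True
        rot = np.zeros((160, 160), dtype=bool)
        rr, cc = draw_ellipse(80, 80, 15, 45, rotation=math.pi / 4)
        rot[rr, cc] = True
        m0, m45 = _measure_mask(base), _measure_mask(rot)
        assert abs(m45.circularity / m0.circularity - 1) < 0.10
        assert abs(m45.aspect_ratio / m0.aspect_ratio - 1) < 0.10

    def test_scale_consistency_exact(self):
        mask = np.pad(disk(10), 2)
        m1 = _measure_mask(mask, mm_per_px=0.1)
        m2 = _measure_mask(mask, mm_per_px=0.2)
        assert m2.length_mm == pytest.approx(2 * m1.length_mm)
        assert m2.area_mm2 == pytest.approx(4 * m1.area_mm2)
        assert m2.circularity == pytest.approx(m1.circularity)  # px-based

    def test_degenerate_single_pixel(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[4, 4] = True
        m = _measure_mask(mask)
        assert m.degenerate
        assert m.length_mm == pytest.approx(0.1)
        assert m.aspect_ratio == 1.0

    def test_missing_label_error(self):
        with pytest.raises(DataError):
            _measure_mask(np.zeros((9, 9), dtype=bool))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    def test_uniform_image_no_candidates(self, uniform_lab):
        seg = segment_candidates(uniform_lab, np.ones((120, 120), bool),
                                 SegmentationParams(), 0.1)
        assert seg.n_objects == 0

    def test_planted_spot_recovered(self):
        spec = ImageSpec(object_requests=[ObjectRequest("spot", 1)], seed=9)
        image, planted = generate_labeled_image(spec)
        lab = rgb_to_lab(image)
        seg = segment_candidates(lab, image.roi_mask(),
                                 SegmentationParams(), image.mm_per_px)
        assert seg.n_objects == 1
        detected = seg.labels == 1
        inter = (detected & planted[0].mask).sum()
        union = (detected | planted[0].mask).sum()
        assert inter / union >= 0.8

    def test_two_objects_two_labels(self):
        spec = ImageSpec(object_requests=[ObjectRequest("spot", 2)], seed=21)
        image, planted = generate_labeled_image(spec)
        seg = segment_candidates(rgb_to_lab(image), image.roi_mask(),
                                 SegmentationParams(), image.mm_per_px)
        assert seg.n_objects == 2

    def test_smoothing_scale_must_exceed_feature_size(self, uniform_lab):
        with pytest.raises(ConfigurationError, match="5"):
            segment_candidates(uniform_lab, np.ones((120, 120), bool),
                               SegmentationParams(smoothing_scale_mm=4.0), 0.1)

    def test_border_touching_flagged(self, uniform_lab):
        lab = uniform_lab.copy()
        lab[0:12, 40:52, 0] -= 10.0  # block on the image edge
        seg = segment_candidates(lab, np.ones((120, 120), bool),
                                 SegmentationParams(), 0.1)
        assert seg.n_objects == 1
        assert 1 in seg.border_labels


def test_end_to_end_ground_truth_roundtrip(four_class_image, analyze):
    """Planted class labels survive the whole measurement chain."""
    image, planted = four_class_image
    result = analyze(image)
    matches = match_planted_to_detected(result, planted)
    for p, row in matches:
        assert row is not None, f"{p.object_class} not detected"
        assert row["object_class"] == p.object_class
        assert row["area_mm2"] == pytest.approx(p.nominal_area_mm2, rel=0.15)
        assert row["surround_delta_e"] == pytest.approx(
            p.nominal_delta_e, rel=0.1)
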