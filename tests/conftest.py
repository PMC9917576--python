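"""Shared fixtures: small synthetic images and cohorts built at test time."""

import numpy as np
import pandas as pd
import pytest

from skinaging import (ImageSpec, ObjectRequest, RunConfig,
                       generate_labeled_image, run_image_pipeline)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_lab():
    """Flat mid-skin Lab raster, 120x120."""
    lab = np.empty((120, 120, 3))
    lab[...] = (60.0, 13.0, 20.0)
    return lab


@pytest.fixture
def four_class_image():
    """One isolated object of each class plus its ground truth."""
    spec = ImageSpec(object_requests=[
        ObjectRequest("wrinkle", 1), ObjectRequest("spot", 1),
        ObjectRequest("pore", 1), ObjectRequest("texture", 1)], seed=42)
    return generate_labeled_image(spec)


@pytest.fixture
def tidy_cohort_small():
    """Hand-built tidy cohort: 3 subjects, 2 timepoints, 1 parameter."""
    rows = []
    for sid, (a, b) in zip("ABC", [(10.0, 11.0), (10.0, 12.0), (10.0, 13.0)]):
        rows.append({"subject_id": sid, "timepoint": "1999",
                     "parameter": "hydration", "value": a})
        rows.append({"subject_id": sid, "timepoint": "0M",
                     "parameter": "hydration", "value": b})
    return pd.DataFrame(rows)


def match_planted_to_detected(result, planted):
    """Map each planted object to the detected label with maximal overlap.

    Returns a list of (planted, detected_row_or_None).
    """
    out = []
    for p in planted:
        ids, counts = np.unique(result.labels[p.mask], return_counts=True)
        weighted = counts * (ids > 0)
        if not weighted.any():
            out.append((p, None))
            continue
        best = int(ids[np.argmax(weighted)])
        row = result.objects[result.objects["label"] == best].iloc[0]
        out.append((p, row))
    return out


@pytest.fixture
def analyze():
    """Run the default image pipeline on a SkinImage."""
    def _run(image, **config_kwargs):
        return run_image_pipeline(RunConfig(**config_kwargs), image)
    return _run
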