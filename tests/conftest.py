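"""Shared fixtures: phantoms and their segmentations.

The small phantom (one bifurcation, 0.05 mm voxels) keeps unit tests fast;
the default phantom (three bifurcations, 0.025 mm voxels, seed 1) is the
full study condition and is segmented once per session for the
pipeline-fidelity tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from corallum import morphometrics as morpho
from corallum import segmentation as seg
from corallum.phantom import PhantomSpec, generate_branch_tree, rasterize_colony


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(tree_depth=1, rng_seed=1, voxel_spacing_mm=0.05)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    tree = generate_branch_tree(small_spec)
    volume, truth = rasterize_colony(tree, small_spec)
    return volume, truth


@pytest.fixture(scope="session")
def small_segmented(small_phantom):
    volume, truth = small_phantom
    chambers = seg.segment_volume(volume)
    return volume, truth, chambers


@pytest.fixture(scope="session")
def small_records(small_segmented):
    volume, truth, chambers = small_segmented
    records = morpho.compute_features(chambers)
    records = morpho.measure_all_calices(records, chambers)
    return records


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(rng_seed=1)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    tree = generate_branch_tree(default_spec)
    volume, truth = rasterize_colony(tree, default_spec)
    return volume, truth


@pytest.fixture(scope="session")
def default_segmented(default_phantom):
    volume, truth = default_phantom
    chambers = seg.segment_volume(volume)
    return volume, truth, chambers


@pytest.fixture(scope="session")
def default_records(default_segmented):
    volume, truth, chambers = default_segmented
    records = morpho.compute_features(chambers)
    records = morpho.measure_all_calices(records, chambers)
    return records


def match_truth_to_predictions(truth, chambers) -> pd.DataFrame:
    """Greedy 1-to-1 matching of true chambers to predicted labels by IoU."""
    rows = []
    used: set[int] = set()
    labels = chambers.labels
    for c in truth.chambers:
        mask = truth.chamber_labels == c.chamber_id
        n_true = int(mask.sum())
        ids, counts = np.unique(labels[mask], return_counts=True)
        sel = ids > 0
        if not sel.any():
            rows.append(
                {"chamber_id": c.chamber_id, "pred_id": 0, "iou": 0.0,
                 "n_true": n_true, "n_pred": 0, "one_to_one": False}
            )
            continue
        best = int(ids[sel][np.argmax(counts[sel])])
        inter = int(counts[sel].max())
        n_pred = int((labels == best).sum())
        iou = inter / (n_true + n_pred - inter)
        one_to_one = best not in used
        used.add(best)
        rows.append(
            {"chamber_id": c.chamber_id, "pred_id": best, "iou": iou,
             "n_true": n_true, "n_pred": n_pred, "one_to_one": one_to_one}
        )
    return pd.DataFrame(rows)
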