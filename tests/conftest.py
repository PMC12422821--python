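"""Shared fixtures: small rendered fields with ground truth, matching helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from senesceope import (generate_field, get_preset, segment_nuclei,
                        expand_to_cell_region, extract_features)
from senesceope.segmentation import SegmentationParams


def match_to_truth(cells: pd.DataFrame, truth: pd.DataFrame, max_dist: float = 5.0):
    """Match segmented cells to truth rows by nearest centroid.

    Returns (matched mask over cells, truth row indices per cell).
    """
    tree = cKDTree(truth[["centroid_row", "centroid_col"]].to_numpy())
    d, idx = tree.query(cells[["centroid_row", "centroid_col"]].to_numpy())
    return d < max_dist, idx


@pytest.fixture(scope="session")
def ir_field_truth():
    """One default-density senescent (IR-G2-E) field plus its ground truth."""
    config = get_preset("IR-G2-E")
    field, truth = generate_field(config, 400, np.random.default_rng(42))
    return config, field, truth


@pytest.fixture(scope="session")
def ir_segmentation(ir_field_truth):
    _, field, _ = ir_field_truth
    return segment_nuclei(field.channel("dna"), SegmentationParams(),
                          field_id=field.field_id)


@pytest.fixture(scope="session")
def ir_cells(ir_field_truth, ir_segmentation):
    config, field, _ = ir_field_truth
    regions = expand_to_cell_region(ir_segmentation, config.cell_expand_px)
    return extract_features(field, ir_segmentation, regions)
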