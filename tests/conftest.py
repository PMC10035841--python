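"""Shared fixtures: expensive synthetic artifacts are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from blastospat import get_preset
from blastospat.morphometry import segment_cells
from blastospat.segmentation import (
    FilterParams,
    SegmentationParams,
    preprocess_stack,
    segment_nuclei,
)
from blastospat.synthetic import generate_membrane_image, generate_nuclear_stack


@pytest.fixture(scope="session")
def wt_late():
    return get_preset("wt_late")


@pytest.fixture(scope="session")
def dorsal_stack(wt_late):
    """One wt_late dorsal nuclear stack with ground truth (seed 1)."""
    return generate_nuclear_stack(wt_late, side="dorsal", field_px=(220, 220), n_slices=12, seed=1)


@pytest.fixture(scope="session")
def dorsal_segmentation(dorsal_stack):
    stack, truth = dorsal_stack
    records = segment_nuclei(preprocess_stack(stack, FilterParams.dorsal()), SegmentationParams.dorsal())
    return records, truth


@pytest.fixture(scope="session")
def membrane_pair(wt_late):
    """Gap-free wt_late dorsal and ventral membrane images with truth (seed 1)."""
    dorsal = generate_membrane_image(wt_late, side="dorsal", stage="late", seed=1, gap_prob=0.0)
    ventral = generate_membrane_image(wt_late, side="ventral", stage="late", seed=1, gap_prob=0.0)
    return dorsal, ventral


@pytest.fixture(scope="session")
def membrane_cells(membrane_pair):
    (img_d, _), (img_v, _) = membrane_pair
    return segment_cells(img_d), segment_cells(img_v)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
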