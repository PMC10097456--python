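from __future__ import annotations

import numpy as np
import pytest

from radiomodal import (
    ACTION_FEATURE_ORDER,
    ActionSequence,
    ConfusionMatrix,
    action_label,
    diagnosis_properties,
)


@pytest.fixture(scope="session")
def props():
    """The bundled diagnosis property set."""
    return diagnosis_properties()


@pytest.fixture(scope="session")
def reference_cm():
    """The reference confusion matrix (group B positive): 21/26 and 14/21 correct."""
    return ConfusionMatrix(tp=21, fp=7, tn=14, fn=5)


def sequence_from_levels(patient_id: str, slice_levels) -> ActionSequence:
    """Build an ActionSequence from per-slice 5-tuples of levels, ordered
    (sphericity, kurtosis, skewness, elongation, mesh_surface)."""
    actions = [
        action_label(feat, int(level))
        for levels in slice_levels
        for feat, level in zip(ACTION_FEATURE_ORDER, levels)
    ]
    return ActionSequence(patient_id, tuple(actions))


@pytest.fixture()
def make_sequence():
    return sequence_from_levels


@pytest.fixture()
def satisfier_levels():
    """Four high-sphericity/low-kurtosis pairs, clean restricted phase."""
    pair = (3, 1, 2, 2, 2)
    calm = (2, 2, 2, 2, 2)
    return [pair, calm, pair, calm, pair, pair, calm]


def disk_mask(radius_px: int, pad: int = 3) -> np.ndarray:
    span = radius_px + pad
    yy, xx = np.mgrid[-span : span + 1, -span : span + 1]
    return ((yy**2 + xx**2) <= radius_px**2).astype(np.uint8)
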