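"""Equal-width 3-level discretization of feature values into action alphabets.

Each feature is split into three equal-width intervals — low, basal, up —
fitted on the *cohort-wide* min/max so that levels are comparable across
patients (the shared disease property requires this).  Level ``k`` of feature
``f`` becomes the action label ``b{k}of3{f}`` (e.g. ``b3of3sphericity``), and
each slice emits its five actions in the fixed order sphericity, kurtosis,
skewness, elongation, meshsurface.

Conventions: a value equal to an interior edge falls in the upper bin; the
maximum maps to level 3; values outside a stored scheme's range are clamped;
a constant feature column is degenerate and always maps to level 2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import RadiomodalError
from .features import (
    ACTION_FEATURE_ORDER,
    FEATURE_ACTION_NAMES,
    FEATURE_COLUMNS,
    validate_feature_table,
)

ACTION_RE = re.compile(r"^b([123])of3(sphericity|kurtosis|skewness|elongation|meshsurface)$")

#: Action-label feature names in within-slice emission order.
ACTION_NAME_ORDER = tuple(FEATURE_ACTION_NAMES[c] for c in ACTION_FEATURE_ORDER)


def action_label(feature: str, level: int) -> str:
    """``(feature column, level)`` → action label, e.g. ``("mesh_surface", 3)`` → ``b3of3meshsurface``."""
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1..3, got {level}")
    name = FEATURE_ACTION_NAMES.get(feature, feature)
    if name not in ACTION_NAME_ORDER:
        raise ValueError(f"unknown feature {feature!r}")
    return f"b{level}of3{name}"


def parse_action_label(label: str) -> tuple[int, str]:
    """Action label → ``(level, feature action-name)``; rejects anything off-grammar."""
    m = ACTION_RE.match(label)
    if not m:
        raise ValueError(f"not a valid action label: {label!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class FeatureBins:
    """Equal-width 3-bin edges for one feature."""

    lower: float
    upper: float
    degenerate: bool = False

    @property
    def edges(self) -> tuple[float, float]:
        width = (self.upper - self.lower) / 3.0
        return (self.lower + width, self.lower + 2.0 * width)

    def level(self, value: float) -> int:
        if self.degenerate:
            return 2
        v = min(max(value, self.lower), self.upper)  # clamp out-of-range values
        e1, e2 = self.edges
        if v < e1:
            return 1
        if v < e2:
            return 2
        return 3


@dataclass(frozen=True)
class BinningScheme:
    """Per-feature equal-width 3-bin partitions fitted on a cohort."""

    bins: Mapping[str, FeatureBins]

    def level(self, feature: str, value: float) -> int:
        return self.bins[feature].level(value)

    def to_json(self) -> str:
        doc = {
            feat: {
                "lower": fb.lower,
                "upper": fb.upper,
                "edges": list(fb.edges),
                "degenerate": fb.degenerate,
            }
            for feat, fb in self.bins.items()
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BinningScheme":
        doc = json.loads(text)
        return cls(
            {
                feat: FeatureBins(d["lower"], d["upper"], d.get("degenerate", False))
                for feat, d in doc.items()
            }
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "BinningScheme":
        return cls.from_json(Path(path).read_text())


def fit_bins(table: pd.DataFrame) -> BinningScheme:
    """Fit cohort-wide equal-width bins on every feature column.

    Bounds are the min/max over all slices of all patients; interior edges sit
    at one and two thirds of the range.  A constant column is marked
    degenerate (every value maps to the basal level).
    """
    table = validate_feature_table(table)
    bins = {}
    for feat in FEATURE_COLUMNS:
        col = table[feat].astype(float)
        lo, hi = float(col.min()), float(col.max())
        bins[feat] = FeatureBins(lo, hi, degenerate=(lo == hi))
    return BinningScheme(bins)


def assign_levels(table: pd.DataFrame, scheme: BinningScheme) -> pd.DataFrame:
    """Replace each feature value by its level 1..3 under ``scheme``."""
    table = validate_feature_table(table)
    out = table[["patient_id", "slice_index"]].copy()
    for feat in FEATURE_COLUMNS:
        fb = scheme.bins[feat]
        out[feat] = [fb.level(v) for v in table[feat].astype(float)]
    return out


@dataclass(frozen=True)
class ActionSequence:
    """A patient's ordered action chain with per-slice boundaries.

    ``slice_boundaries[i]`` is the index of the first action of the i-th
    slice; every slice contributes exactly five actions.
    """

    patient_id: str
    actions: tuple[str, ...]
    slice_boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self):
        for a in self.actions:
            parse_action_label(a)
        if len(self.actions) % len(ACTION_NAME_ORDER) != 0:
            raise ValueError("sequence length must be a multiple of 5")
        n_slices = len(self.actions) // len(ACTION_NAME_ORDER)
        expected = tuple(5 * i for i in range(n_slices))
        if self.slice_boundaries == ():
            object.__setattr__(self, "slice_boundaries", expected)
        elif self.slice_boundaries != expected:
            raise ValueError("slice boundaries inconsistent with 5 actions per slice")

    @property
    def n_slices(self) -> int:
        return len(self.actions) // len(ACTION_NAME_ORDER)


def to_action_sequence(levelled: pd.DataFrame) -> ActionSequence:
    """Turn one patient's levelled rows into its action chain.

    Rows are ordered by ascending slice index; within a slice, actions are
    emitted in the fixed feature order (sphericity, kurtosis, skewness,
    elongation, meshsurface).
    """
    missing = ({"patient_id", "slice_index"} | set(FEATURE_COLUMNS)) - set(levelled.columns)
    if missing:
        raise RadiomodalError(f"levelled rows missing columns: {sorted(missing)}")
    patients = levelled["patient_id"].unique()
    if len(patients) != 1:
        raise RadiomodalError("to_action_sequence expects rows of exactly one patient")
    rows = levelled.sort_values("slice_index")
    actions: list[str] = []
    for _, row in rows.iterrows():
        for feat in ACTION_FEATURE_ORDER:
            actions.append(action_label(feat, int(row[feat])))
    return ActionSequence(str(patients[0]), tuple(actions))


def cohort_action_sequences(levelled: pd.DataFrame) -> dict[str, ActionSequence]:
    """One ActionSequence per patient, keyed by patient id."""
    return {
        str(pid): to_action_sequence(group)
        for pid, group in levelled.groupby("patient_id", sort=True)
    }
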