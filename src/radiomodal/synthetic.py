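"""Synthetic labelled cohorts for exercising the pipeline end to end.

Two generation modes:

* **sequence mode** — draws each patient's discretized action chain directly.
  A configurable fraction of each group are "satisfiers": their chains embed
  the pattern the bundled disease property looks for (four consecutive
  high-sphericity/low-kurtosis slice pairs, with no stray occurrences of
  those two actions once the restricted-recursion phase starts).
  Non-satisfiers are drawn uniformly and *verified* not to satisfy the entry
  property by running the checker in a bounded rejection loop — the negation
  of the property has no convenient closed form.  Every generated patient's
  ground-truth flag therefore agrees with the checker by construction.
* **image mode** — draws per-slice elliptical lesions (axis ratio drives
  elongation/sphericity, area drives mesh surface) filled with skew-normal
  intensities (shape parameter drives skewness/kurtosis) on a noisy
  background, exercising feature extraction and every downstream stage.
  Image mode does not attempt to realize a prescribed discretized pattern
  (an inverse problem); group labels there carry no property guarantee.

Cohorts are reproducible bit-for-bit from ``(spec, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ccs import build_process, to_lts, write_ccs_model
from .discretize import (
    ACTION_FEATURE_ORDER,
    ActionSequence,
    action_label,
    cohort_action_sequences,
    fit_bins,
    assign_levels,
)
from .errors import GenerationError
from .features import (
    PreprocessConfig,
    SliceImage,
    SliceMask,
    extract_cohort_features,
    write_labels,
)
from .metrics import MetricsReport, classification_metrics, confusion_matrix
from .mucalc import PropRef, PropertySet, check_patient, satisfying_states, diagnosis_properties


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults mirror the reference cohort: 21 group-A and 26 group-B patients
    with per-group property-satisfaction rates 7/21 and 21/26, and 5–20
    slices per exam (a plausible extremity-MRI stack depth).
    """

    n_group_a: int = 21
    n_group_b: int = 26
    p_pattern_a: float = 7 / 21
    p_pattern_b: float = 21 / 26
    fixed_satisfier_counts: bool = False
    slices_min: int = 5
    slices_max: int = 20
    mode: str = "sequence"
    seed: int = 0
    # image-mode knobs
    frame_shape: tuple[int, int] = (96, 96)
    spacing: tuple[float, float] = (0.6, 0.6)
    axis_ratio_range: tuple[float, float] = (0.4, 1.0)
    area_range: tuple[float, float] = (50.0, 500.0)  # mm^2
    intensity_loc: float = 100.0
    intensity_scale: float = 20.0
    intensity_shape_range: tuple[float, float] = (-5.0, 5.0)
    # background emulates surrounding tissue signal: nonzero mean keeps the
    # lesion within the post-normalization clipping range
    background_mean: float = 60.0
    background_sigma: float = 15.0
    max_attempts: int = 1000

    def __post_init__(self):
        if not (0 <= self.p_pattern_a <= 1 and 0 <= self.p_pattern_b <= 1):
            raise ValueError("pattern probabilities must lie in [0, 1]")
        if self.n_group_a < 0 or self.n_group_b < 0:
            raise ValueError("group sizes must be non-negative")
        if not (1 <= self.slices_min <= self.slices_max):
            raise ValueError("need 1 <= slices_min <= slices_max")
        if self.mode not in ("sequence", "image"):
            raise ValueError("mode must be 'sequence' or 'image'")
        if self.mode == "image":
            extent = min(
                self.frame_shape[0] * self.spacing[0],
                self.frame_shape[1] * self.spacing[1],
            )
            a_max = math.sqrt(
                self.area_range[1] / (math.pi * self.axis_ratio_range[0])
            )
            if 2 * a_max > 0.9 * extent:
                raise GenerationError(
                    "requested lesion area does not fit the image frame"
                )


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Read a CohortSpec from a YAML mapping of field names to values.

    Tuple-valued fields (ranges, shapes, spacing) may be given as YAML lists.
    """
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise GenerationError("cohort spec file must be a YAML mapping")
    valid = {f.name for f in fields(CohortSpec)}
    unknown = set(doc) - valid
    if unknown:
        raise GenerationError(f"unknown cohort spec fields: {sorted(unknown)}")
    converted = {
        k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()
    }
    return CohortSpec(**converted)


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    group: str  # "A" or "B"
    satisfier: bool | None  # None in image mode (no property guarantee)
    sequence: ActionSequence | None = None
    stack: tuple[tuple[SliceImage, SliceMask], ...] | None = None


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    patients: tuple[SyntheticPatient, ...]

    @property
    def labels(self) -> dict[str, str]:
        return {p.patient_id: p.group for p in self.patients}

    @property
    def sequences(self) -> dict[str, ActionSequence]:
        return {
            p.patient_id: p.sequence for p in self.patients if p.sequence is not None
        }


# ---------------------------------------------------------------------------
# Sequence mode


def _satisfier_flags(spec: CohortSpec, n: int, p: float, rng) -> list[bool]:
    if spec.fixed_satisfier_counts:
        k = round(p * n)
        return [i < k for i in range(n)]
    return [bool(v) for v in rng.random(n) < p]


def _draw_levels(rng, n_slices: int) -> np.ndarray:
    return rng.integers(1, 4, size=(n_slices, len(ACTION_FEATURE_ORDER)))


def _levels_to_sequence(patient_id: str, levels: np.ndarray) -> ActionSequence:
    actions = [
        action_label(feat, int(levels[i, j]))
        for i in range(levels.shape[0])
        for j, feat in enumerate(ACTION_FEATURE_ORDER)
    ]
    return ActionSequence(patient_id, tuple(actions))


_SPH, _KUR = 0, 1  # column indices of sphericity and kurtosis in the slice order


def _draw_satisfier_levels(rng, n_slices: int) -> np.ndarray:
    """Levels embedding four high-sphericity/low-kurtosis pairs.

    All non-pair slices avoid the two pattern actions entirely (sphericity
    below 3, kurtosis above 1), which keeps the restricted-recursion phase of
    the property clean regardless of where the pairs fall.
    """
    if n_slices < 4:
        raise GenerationError("satisfier patients need at least 4 slices")
    levels = _draw_levels(rng, n_slices)
    pair_slices = set(rng.choice(n_slices, size=4, replace=False).tolist())
    for i in range(n_slices):
        if i in pair_slices:
            levels[i, _SPH] = 3
            levels[i, _KUR] = 1
        else:
            levels[i, _SPH] = rng.integers(1, 3)  # 1..2
            levels[i, _KUR] = rng.integers(2, 4)  # 2..3
    return levels


def _entry_holds(seq: ActionSequence, props: PropertySet) -> bool:
    lts = to_lts(build_process(seq))
    return 0 in satisfying_states(lts, PropRef(props.entry), props)


def generate_action_cohort(
    spec: CohortSpec, props: PropertySet | None = None
) -> SyntheticCohort:
    """Draw a sequence-mode cohort whose ground truth the checker confirms."""
    if spec.mode != "sequence":
        raise GenerationError("generate_action_cohort requires mode='sequence'")
    props = props or diagnosis_properties()
    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    for group, n, p in (
        ("A", spec.n_group_a, spec.p_pattern_a),
        ("B", spec.n_group_b, spec.p_pattern_b),
    ):
        flags = _satisfier_flags(spec, n, p, rng)
        for i, satisfier in enumerate(flags):
            pid = f"{group}{i + 1:03d}"
            n_slices = int(rng.integers(spec.slices_min, spec.slices_max + 1))
            if satisfier:
                seq = _levels_to_sequence(pid, _draw_satisfier_levels(rng, max(n_slices, 4)))
                if not _entry_holds(seq, props):
                    raise GenerationError(
                        f"constructed satisfier {pid} rejected by the checker"
                    )
            else:
                for _ in range(spec.max_attempts):
                    seq = _levels_to_sequence(pid, _draw_levels(rng, n_slices))
                    if not _entry_holds(seq, props):
                        break
                else:
                    raise GenerationError(
                        f"could not draw a non-satisfying sequence for {pid} "
                        f"in {spec.max_attempts} attempts"
                    )
            patients.append(SyntheticPatient(pid, group, satisfier, sequence=seq))
    return SyntheticCohort(spec, tuple(patients))


# ---------------------------------------------------------------------------
# Image mode


def _ellipse_mask(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    area: float,
    ratio: float,
    theta: float,
    center: tuple[float, float],
) -> np.ndarray:
    a = math.sqrt(area / (math.pi * ratio))  # semi-major axis, mm
    b = ratio * a
    rows = np.arange(shape[0])[:, None] * spacing[0]
    cols = np.arange(shape[1])[None, :] * spacing[1]
    y = rows - center[0]
    x = cols - center[1]
    u = y * math.cos(theta) + x * math.sin(theta)
    v = -y * math.sin(theta) + x * math.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def generate_image_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw an image-mode cohort of elliptical lesions on noisy backgrounds."""
    if spec.mode != "image":
        raise GenerationError("generate_image_cohort requires mode='image'")
    rng = np.random.default_rng(spec.seed)
    center = (
        spec.frame_shape[0] * spec.spacing[0] / 2.0,
        spec.frame_shape[1] * spec.spacing[1] / 2.0,
    )
    patients: list[SyntheticPatient] = []
    for group, n in (("A", spec.n_group_a), ("B", spec.n_group_b)):
        for i in range(n):
            pid = f"{group}{i + 1:03d}"
            n_slices = int(rng.integers(spec.slices_min, spec.slices_max + 1))
            stack = []
            for k in range(n_slices):
                ratio = rng.uniform(*spec.axis_ratio_range)
                area = rng.uniform(*spec.area_range)
                theta = rng.uniform(0.0, math.pi)
                mask = _ellipse_mask(
                    spec.frame_shape, spec.spacing, area, ratio, theta, center
                )
                if not mask.any():
                    raise GenerationError(f"degenerate empty lesion for {pid}")
                shape_param = rng.uniform(*spec.intensity_shape_range)
                pixels = rng.normal(
                    spec.background_mean, spec.background_sigma, spec.frame_shape
                )
                inside = int(mask.sum())
                pixels[mask > 0] = stats.skewnorm.rvs(
                    shape_param,
                    loc=spec.intensity_loc,
                    scale=spec.intensity_scale,
                    size=inside,
                    random_state=rng,
                )
                stack.append(
                    (
                        SliceImage(pixels, spec.spacing, slice_index=k),
                        SliceMask(mask, spec.spacing),
                    )
                )
            patients.append(
                SyntheticPatient(pid, group, satisfier=None, stack=tuple(stack))
            )
    return SyntheticCohort(spec, tuple(patients))


# ---------------------------------------------------------------------------
# End-to-end evaluation


@dataclass(frozen=True)
class EndToEndResult:
    report: MetricsReport
    predictions: Mapping[str, str]
    verdicts: Mapping[str, bool]


def evaluate_end_to_end(
    cohort: SyntheticCohort,
    props: PropertySet | None = None,
    config: PreprocessConfig | None = None,
) -> EndToEndResult:
    """Run the full pipeline on a synthetic cohort and score it.

    Image-mode cohorts go through feature extraction and cohort-wide
    discretization first; sequence-mode cohorts are already discretized.
    Each patient's chain is unfolded to its LTS, checked against the entry
    property, and a true verdict predicts group B.
    """
    props = props or diagnosis_properties()
    if cohort.spec.mode == "image":
        stacks = {p.patient_id: list(p.stack) for p in cohort.patients}
        table = extract_cohort_features(stacks, config or PreprocessConfig())
        scheme = fit_bins(table)
        sequences = cohort_action_sequences(assign_levels(table, scheme))
    else:
        sequences = cohort.sequences
    verdicts: dict[str, bool] = {}
    for pid in sorted(sequences):
        lts = to_lts(build_process(sequences[pid]))
        verdicts[pid] = check_patient(lts, props).verdict
    predictions = {pid: ("B" if v else "A") for pid, v in verdicts.items()}
    cm = confusion_matrix(cohort.labels, predictions)
    return EndToEndResult(classification_metrics(cm), predictions, verdicts)


# ---------------------------------------------------------------------------
# Persistence


def save_action_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a sequence-mode cohort as a .ccs model file plus labels CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_path = outdir / "cohort.ccs"
    labels_path = outdir / "labels.csv"
    processes = [build_process(seq) for _, seq in sorted(cohort.sequences.items())]
    model_path.write_text(write_ccs_model(processes))
    write_labels(cohort.labels, labels_path)
    truth = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "group": [p.group for p in cohort.patients],
            "satisfier": [p.satisfier for p in cohort.patients],
        }
    )
    truth_path = outdir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    return {"model": model_path, "labels": labels_path, "ground_truth": truth_path}


def save_image_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write an image-mode cohort as NIfTI image/mask volume pairs."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for p in cohort.patients:
        img = np.stack([s.pixels for s, _ in p.stack], axis=-1)
        msk = np.stack([m.pixels for _, m in p.stack], axis=-1)
        affine = np.diag([p.stack[0][0].spacing[0], p.stack[0][0].spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(img.astype(np.float32), affine), outdir / f"{p.patient_id}_image.nii.gz")
        nib.save(nib.Nifti1Image(msk.astype(np.uint8), affine), outdir / f"{p.patient_id}_mask.nii.gz")
        paths[p.patient_id] = outdir / f"{p.patient_id}_image.nii.gz"
    write_labels(cohort.labels, outdir / "labels.csv")
    return paths
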