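"""End-to-end orchestration: features → levels → models → verdicts → metrics.

Each stage writes its artifact in the format the matching module reads back,
so partial runs can be inspected and resumed; a manifest records the exact
configuration, its hash, the seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from .ccs import build_process, parse_ccs_model, to_lts, write_ccs_model
from .discretize import (
    BinningScheme,
    assign_levels,
    cohort_action_sequences,
    fit_bins,
)
from .errors import RadiomodalError
from .features import (
    FEATURE_COLUMNS,
    PreprocessConfig,
    extract_cohort_features,
    load_nifti_stack,
    read_feature_table,
    read_labels,
    write_feature_table,
)
from .metrics import classification_metrics, confusion_matrix, spearman_matrix
from .mucalc import check_patient, localize, read_properties, diagnosis_properties

logger = logging.getLogger("radiomodal")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (exactly one input modality)."""

    labels_csv: Path
    outdir: Path
    features_csv: Path | None = None
    images_dir: Path | None = None
    property_file: Path | None = None  # None → bundled diagnosis property
    binning_scheme: Path | None = None  # None → fit on this cohort
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0

    def __post_init__(self):
        if (self.features_csv is None) == (self.images_dir is None):
            raise RadiomodalError(
                "exactly one input modality required: --features or --images"
            )

    def digest(self) -> str:
        doc = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def discover_image_pairs(images_dir: Path) -> dict[str, tuple[Path, Path]]:
    """Find ``<patient>_image.nii[.gz]`` / ``<patient>_mask.nii[.gz]`` pairs."""
    pairs: dict[str, tuple[Path, Path]] = {}
    for img in sorted(images_dir.glob("*_image.nii*")):
        pid = img.name.split("_image.nii")[0]
        for suffix in (".nii.gz", ".nii"):
            mask = images_dir / f"{pid}_mask{suffix}"
            if mask.exists():
                pairs[pid] = (img, mask)
                break
        else:
            raise RadiomodalError(f"no mask volume found for patient {pid!r}")
    if not pairs:
        raise RadiomodalError(f"no image/mask pairs found in {images_dir}")
    return pairs


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, *exc):
            self.elapsed = time.perf_counter() - self.t0
            logger.info("stage %s: done in %.2fs", name, self.elapsed)

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the full output tree; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    labels = read_labels(config.labels_csv)

    with _stage("features") as t:
        if config.features_csv is not None:
            table = read_feature_table(config.features_csv)
        else:
            pairs = discover_image_pairs(Path(config.images_dir))
            stacks = {
                pid: load_nifti_stack(img, mask) for pid, (img, mask) in pairs.items()
            }
            table = extract_cohort_features(stacks, config.preprocess)
        write_feature_table(table, outdir / "features.csv")
    timings["features"] = t.elapsed

    missing = set(table["patient_id"].astype(str)) - set(labels)
    if missing:
        raise RadiomodalError(f"patients without labels: {sorted(missing)[:5]}")

    with _stage("discretize") as t:
        if config.binning_scheme is not None:
            scheme = BinningScheme.load(config.binning_scheme)
        else:
            scheme = fit_bins(table)
        scheme.save(outdir / "binning_scheme.json")
        levels = assign_levels(table, scheme)
        levels.to_csv(outdir / "levels.csv", index=False)
        sequences = cohort_action_sequences(levels)
    timings["discretize"] = t.elapsed

    with _stage("model") as t:
        processes = {pid: build_process(seq) for pid, seq in sequences.items()}
        (outdir / "cohort.ccs").write_text(
            write_ccs_model(processes[pid] for pid in sorted(processes))
        )
    timings["model"] = t.elapsed

    with _stage("check") as t:
        props = (
            read_properties(config.property_file)
            if config.property_file is not None
            else diagnosis_properties()
        )
        verdicts: dict[str, dict] = {}
        for pid in sorted(sequences):
            lts = to_lts(processes[pid])
            result = check_patient(lts, props)
            slices = localize(lts, props)
            verdicts[pid] = {
                **result.to_dict(),
                "predicted_group": "B" if result.verdict else "A",
                "slices": {name: sorted(s) for name, s in slices.items()},
            }
        (outdir / "verdicts.json").write_text(json.dumps(verdicts, indent=2))
    timings["check"] = t.elapsed

    with _stage("metrics") as t:
        predictions = {pid: v["predicted_group"] for pid, v in verdicts.items()}
        truth = {pid: labels[pid] for pid in predictions}
        report = classification_metrics(confusion_matrix(truth, predictions))
        (outdir / "metrics.json").write_text(report.to_json())
        (outdir / "metrics.txt").write_text(report.to_text() + "\n")
        spearman_matrix(table).to_csv(outdir / "spearman.csv")
    timings["metrics"] = t.elapsed

    manifest = {
        "config": {k: str(v) for k, v in asdict(config).items()},
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {"radiomodal": _pkg_version, "pandas": pd.__version__},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_patients": len(verdicts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "metrics": report.rounded(),
        "confusion_matrix": vars(report.cm),
        "verdicts": verdicts,
        "manifest": manifest,
    }
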