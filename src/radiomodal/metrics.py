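"""Classification metrics, clinical utility indices and feature correlation.

Group B ("metastases/local recurrence") is the positive class throughout.
Beyond the usual panel (sensitivity, specificity, accuracy, PPV, NPV) the
report carries the clinical utility indices

    CUI+ = sensitivity × PPV        CUI− = specificity × NPV

graded on the standard bands: excellent (≥ 0.81), good (≥ 0.64),
satisfactory/fair (≥ 0.49), poor (< 0.49) and very poor (≤ 0.36); the two
lowest bands overlap as printed, so a value ≤ 0.36 is graded very poor and
anything else below 0.49 poor.  Metrics with a zero denominator are reported
as undefined (``None``) rather than raised.  Display rounding is half-up to
2 decimals (3 for the CUIs); raw values are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RadiomodalError
from .features import FEATURE_COLUMNS

POSITIVE_GROUP = "B"
NEGATIVE_GROUP = "A"

CUI_BANDS = (
    (0.81, "excellent"),
    (0.64, "good"),
    (0.49, "satisfactory/fair"),
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with group B as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_matrix(
    truth: Mapping[str, str], predicted: Mapping[str, str]
) -> ConfusionMatrix:
    """Tally per-patient group labels (A/B) into a confusion matrix."""
    if set(truth) != set(predicted):
        raise RadiomodalError("truth and predictions cover different patients")
    counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for pid, actual in truth.items():
        pred = predicted[pid]
        for label in (actual, pred):
            if label not in (POSITIVE_GROUP, NEGATIVE_GROUP):
                raise RadiomodalError(f"unknown group label {label!r} for patient {pid!r}")
        if actual == POSITIVE_GROUP:
            counts["tp" if pred == POSITIVE_GROUP else "fn"] += 1
        else:
            counts["fp" if pred == POSITIVE_GROUP else "tn"] += 1
    return ConfusionMatrix(**counts)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def round_half_up(value: float, decimals: int) -> float:
    """Round half away from zero at the printed precision (0.605… → 0.61)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def grade_cui(value: float | None) -> str | None:
    """Clinical-utility grade of a CUI value."""
    if value is None:
        return None
    for threshold, label in CUI_BANDS:
        if value >= threshold:
            return label
    return "very poor" if value <= 0.36 else "poor"


@dataclass(frozen=True)
class MetricsReport:
    """Raw metric panel; ``None`` marks an undefined (0/0) entry."""

    cm: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    cui_positive: float | None
    cui_negative: float | None

    @property
    def cui_positive_grade(self) -> str | None:
        return grade_cui(self.cui_positive)

    @property
    def cui_negative_grade(self) -> str | None:
        return grade_cui(self.cui_negative)

    def rounded(self) -> dict[str, float | str | None]:
        """Display panel at the conventional precision (2 dp, 3 for CUIs)."""
        r2 = lambda v: None if v is None else round_half_up(v, 2)
        r3 = lambda v: None if v is None else round_half_up(v, 3)
        return {
            "sensitivity": r2(self.sensitivity),
            "specificity": r2(self.specificity),
            "accuracy": r2(self.accuracy),
            "ppv": r2(self.ppv),
            "npv": r2(self.npv),
            "cui_positive": r3(self.cui_positive),
            "cui_negative": r3(self.cui_negative),
            "cui_positive_grade": self.cui_positive_grade,
            "cui_negative_grade": self.cui_negative_grade,
        }

    def to_json(self) -> str:
        doc = {
            "confusion_matrix": vars(self.cm),
            "raw": {
                k: getattr(self, k)
                for k in (
                    "sensitivity",
                    "specificity",
                    "accuracy",
                    "ppv",
                    "npv",
                    "cui_positive",
                    "cui_negative",
                )
            },
            "display": self.rounded(),
        }
        return json.dumps(doc, indent=2)

    def to_text(self) -> str:
        d = self.rounded()
        cm = self.cm
        lines = [
            "            predicted B  predicted A",
            f"actual B    {cm.tp:>11d}  {cm.fn:>11d}",
            f"actual A    {cm.fp:>11d}  {cm.tn:>11d}",
            "",
        ]
        for key in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            lines.append(f"{key:<12} {d[key]}")
        lines.append(f"{'CUI+':<12} {d['cui_positive']} ({d['cui_positive_grade']})")
        lines.append(f"{'CUI-':<12} {d['cui_negative']} ({d['cui_negative_grade']})")
        return "\n".join(lines)


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the full metric panel (with CUIs) from a confusion matrix."""
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.tn + cm.fp)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    cui_pos, cui_neg, _ = clinical_utility(se, sp, ppv, npv)
    return MetricsReport(cm, se, sp, acc, ppv, npv, cui_pos, cui_neg)


def clinical_utility(
    sensitivity: float | None,
    specificity: float | None,
    ppv: float | None,
    npv: float | None,
) -> tuple[float | None, float | None, dict[str, str | None]]:
    """CUI+ = se·ppv and CUI− = sp·npv, with their utility grades."""
    cui_pos = None if sensitivity is None or ppv is None else sensitivity * ppv
    cui_neg = None if specificity is None or npv is None else specificity * npv
    grades = {"cui_positive": grade_cui(cui_pos), "cui_negative": grade_cui(cui_neg)}
    return cui_pos, cui_neg, grades


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlation of the five features.

    Average ranks on ties; a constant column yields NaN entries (undefined
    correlation), with the diagonal forced to 1 for non-constant columns.
    """
    cols = [c for c in FEATURE_COLUMNS if c in table.columns]
    if len(table) < 3:
        raise RadiomodalError("need at least 3 rows for a rank correlation")
    data = table[cols].astype(float).to_numpy()
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi, xj = data[:, i], data[:, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            rho = stats.spearmanr(xi, xj).statistic if i != j else 1.0
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=cols, columns=cols)
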