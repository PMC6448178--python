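"""Per-site and micro-averaged diagnostic metrics.

Predicted and gold labels are boolean vectors over the twenty skeletal
sites, one vector per patient (the gold standard is abstracted per
subject; a per-document unit exists for debugging).  For each site i the
patients are tabulated into TP/TN/FP/FN and five metrics are derived:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV = TP / (TP + FP)                NPV = TN / (TN + FN)
    F1  = 2 * PPV * sensitivity / (PPV + sensitivity)

Micro-averages pool the counts by summation across sites before applying
the same formulas, so sites contribute in proportion to their counts.
A zero denominator yields an undefined metric, reported as NA and never
coerced to 0 or 1; pooled micro-averages remain well defined regardless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .lexicon import CATEGORY_IDS, DISPLAY_NAMES

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "EvaluationError",
    "confusion_counts",
    "compute_metrics",
    "micro_average",
    "metrics_table",
    "write_report",
    "read_labels_csv",
    "write_labels_csv",
]

PathLike = Union[str, Path]
LabelVector = Mapping[str, bool]

METRIC_COLUMNS = ("Sensitivity", "Specificity", "PPV", "NPV", "F1-score")


class EvaluationError(ValueError):
    """Raised for mismatched prediction/gold inputs."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 patient counts for one site."""

    category: str
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            category="pooled",
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """The five metrics; None marks an undefined (0/0) value."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "PPV": self.ppv,
            "NPV": self.npv,
            "F1-score": self.f1,
        }


def confusion_counts(
    pred: Mapping[str, LabelVector],
    gold: Mapping[str, LabelVector],
    categories: Iterable[str] = CATEGORY_IDS,
) -> dict[str, ConfusionCounts]:
    """Tabulate per-site 2x2 counts over patients.

    *pred* and *gold* map patient id -> label vector and must cover the
    same, non-empty patient set.
    """
    pred_ids = set(pred)
    gold_ids = set(gold)
    if not pred_ids or not gold_ids:
        raise EvaluationError("empty patient set")
    if pred_ids != gold_ids:
        only_pred = sorted(pred_ids - gold_ids)
        only_gold = sorted(gold_ids - pred_ids)
        parts = []
        if only_pred:
            parts.append(f"only in predictions: {', '.join(only_pred)}")
        if only_gold:
            parts.append(f"only in gold: {', '.join(only_gold)}")
        raise EvaluationError("patient sets differ; " + "; ".join(parts))

    counts: dict[str, ConfusionCounts] = {}
    for category in categories:
        tp = tn = fp = fn = 0
        for pid in pred:
            p = bool(pred[pid].get(category, False))
            g = bool(gold[pid].get(category, False))
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
        counts[category] = ConfusionCounts(category, tp=tp, tn=tn, fp=fp, fn=fn)
    return counts


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Apply the five formulas to one 2x2 table.

    F1 is undefined whenever PPV or sensitivity is undefined, or when
    their sum is zero.
    """
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return MetricSet(sens, spec, ppv, npv, f1)


def micro_average(
    all_counts: Mapping[str, ConfusionCounts] | Iterable[ConfusionCounts],
) -> MetricSet:
    """Pool counts by summation across sites, then apply the formulas.

    Equals ``compute_metrics`` of the element-wise summed counts by
    construction.
    """
    if isinstance(all_counts, Mapping):
        items = list(all_counts.values())
    else:
        items = list(all_counts)
    if not items:
        raise EvaluationError("micro_average needs at least one category")
    pooled = ConfusionCounts("pooled")
    for c in items:
        pooled = pooled + c
    return compute_metrics(pooled)


def metrics_table(
    per_category: Mapping[str, MetricSet],
    micro: MetricSet,
    display_names: Mapping[str, str] = DISPLAY_NAMES,
) -> pd.DataFrame:
    """One row per site plus a final Micro-Average row, full precision.

    Rows follow the site order of the default lexicon (alphabetical by
    display name); undefined metrics are NaN here and rendered as "NA" by
    :func:`write_report`.
    """
    rows = []
    index = []
    for category, ms in per_category.items():
        index.append(display_names.get(category, category))
        rows.append(
            {k: (math.nan if v is None else v) for k, v in ms.as_dict().items()}
        )
    index.append("Micro-Average")
    rows.append(
        {k: (math.nan if v is None else v) for k, v in micro.as_dict().items()}
    )
    df = pd.DataFrame(rows, index=index, columns=list(METRIC_COLUMNS))
    df.index.name = "Fractures"
    return df


def write_report(table: pd.DataFrame, path: PathLike) -> None:
    """Write the report CSV, metrics rounded to 3 decimals, NA for undefined."""
    table.to_csv(
        path, float_format="%.3f", na_rep="NA", lineterminator="\n"
    )


def read_labels_csv(
    path: PathLike, categories: Iterable[str] = CATEGORY_IDS
) -> dict[str, dict[str, bool]]:
    """Read a patient x site 0/1 label table keyed by ``patient_id``."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise EvaluationError(f"{path}: missing 'patient_id' column")
    missing = [c for c in categories if c not in df.columns]
    if missing:
        raise EvaluationError(
            f"{path}: missing category column(s): {', '.join(missing)}"
        )
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise EvaluationError(f"{path}: duplicate patient id(s): {dupes}")
    out: dict[str, dict[str, bool]] = {}
    for _, row in df.iterrows():
        out[row["patient_id"]] = {
            c: bool(int(row[c])) for c in categories
        }
    return out


def write_labels_csv(
    labels: Mapping[str, LabelVector],
    path: PathLike,
    categories: Iterable[str] = CATEGORY_IDS,
) -> None:
    """Write patient labels as CSV (patient_id + one 0/1 column per site)."""
    categories = list(categories)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("patient_id," + ",".join(categories) + "\n")
        for pid in sorted(labels):
            vec = labels[pid]
            fh.write(
                pid
                + ","
                + ",".join(str(int(bool(vec.get(c, False)))) for c in categories)
                + "\n"
            )
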