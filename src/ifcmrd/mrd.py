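"""Clinical readouts: residual-disease fractions, cutoff metrics,
confusion matrices, and the channel-ablation study.

The residual-disease (MRD) fraction of a sample is the percentage of
predicted leukemic cells over all evaluated in-focus single cells.  The
clinically decisive readout is the sample-level call at a fraction cutoff
(25% marks slow early responders); the comparison is strict
greater-than on both the prediction and the truth, so a sample at exactly
the cutoff is "not above threshold".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CLASS_LABELS, ValidationError


@dataclass(frozen=True)
class MRDResult:
    patient_id: str
    timepoint_label: str
    n_cells_evaluated: int
    predicted_fraction: float  # percent
    truth_fraction: Optional[float] = None  # percent

    def __post_init__(self) -> None:
        if self.n_cells_evaluated < 1:
            raise ValidationError("n_cells_evaluated must be >= 1")
        if not (0 <= self.predicted_fraction <= 100):
            raise ValidationError("predicted_fraction must be in [0, 100]")
        if self.truth_fraction is not None and not (0 <= self.truth_fraction <= 100):
            raise ValidationError("truth_fraction must be in [0, 100]")


@dataclass(frozen=True)
class CutoffMetrics:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]  # percent, None when TP+FN == 0
    specificity: Optional[float]  # percent, None when TN+FP == 0


def mrd_fraction(
    labels: Sequence[str],
    patient_id: str,
    timepoint_label: str,
    truth_fraction: Optional[float] = None,
) -> MRDResult:
    """Predicted leukemic percentage for one sample's per-cell labels.

    Invariant to cell ordering; errors on an empty sample.
    """
    n = len(labels)
    if n == 0:
        raise ValidationError("cannot compute an MRD fraction over zero cells")
    n_leuk = sum(1 for lb in labels if lb == "leukemic")
    return MRDResult(
        patient_id=patient_id,
        timepoint_label=timepoint_label,
        n_cells_evaluated=n,
        predicted_fraction=100.0 * n_leuk / n,
        truth_fraction=truth_fraction,
    )


def cutoff_metrics(results: Sequence[MRDResult], cutoff: float) -> CutoffMetrics:
    """Sample-level sensitivity/specificity at a fraction cutoff.

    A sample is called positive when its fraction is strictly greater
    than the cutoff, on both the predicted and the truth side.  A rate
    whose denominator is zero is flagged None (undefined).
    """
    if not results:
        raise ValidationError("no MRD results to evaluate")
    tp = fp = tn = fn = 0
    for r in results:
        if r.truth_fraction is None:
            raise ValidationError(
                f"sample ({r.patient_id}, {r.timepoint_label}) lacks truth_fraction"
            )
        pred_pos = r.predicted_fraction > cutoff
        true_pos = r.truth_fraction > cutoff
        if true_pos and pred_pos:
            tp += 1
        elif true_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return CutoffMetrics(
        cutoff=cutoff, tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens, specificity=spec
    )


def evaluate_classification(
    predicted: Sequence[str],
    truth: Sequence[str],
    classes: Sequence[str] = CLASS_LABELS,
) -> dict:
    """3-class confusion matrix (rows = truth, columns = prediction),
    overall accuracy (%), and per-class recall (%)."""
    if len(predicted) != len(truth):
        raise ValidationError("label sequences differ in length")
    idx = {c: i for i, c in enumerate(classes)}
    for lb in (*predicted, *truth):
        if lb not in idx:
            raise ValidationError(f"label {lb!r} outside {tuple(classes)}")
    k = len(classes)
    matrix = np.zeros((k, k), dtype=np.int64)
    for p, t in zip(predicted, truth):
        matrix[idx[t], idx[p]] += 1
    total = matrix.sum()
    accuracy = 100.0 * np.trace(matrix) / total if total else float("nan")
    recall = {}
    for c in classes:
        row = matrix[idx[c]]
        recall[c] = 100.0 * row[idx[c]] / row.sum() if row.sum() else float("nan")
    return {
        "confusion": pd.DataFrame(matrix, index=list(classes), columns=list(classes)),
        "accuracy": accuracy,
        "recall": recall,
    }


def mrd_table(results: Sequence[MRDResult]) -> pd.DataFrame:
    """Per-sample MRD report (TSV-ready)."""
    return pd.DataFrame(
        {
            "patient": [r.patient_id for r in results],
            "timepoint": [r.timepoint_label for r in results],
            "n_cells": [r.n_cells_evaluated for r in results],
            "predicted_pct": [r.predicted_fraction for r in results],
            "truth_pct": [r.truth_fraction for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Channel ablation


@dataclass
class AblationResult:
    """Per-subset accuracies for nested channel subsets (drop order)."""

    subsets: list[tuple[str, ...]] = field(default_factory=list)
    per_entry_accuracy: list[dict[str, float]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for subset, accs in zip(self.subsets, self.per_entry_accuracy):
            vals = np.array(list(accs.values()))
            rows.append(
                {
                    "channels": "+".join(subset),
                    "n_channels": len(subset),
                    "median_accuracy": float(np.median(vals)),
                    "q1_accuracy": float(np.percentile(vals, 25)),
                    "q3_accuracy": float(np.percentile(vals, 75)),
                }
            )
        return pd.DataFrame(rows)

    def long_table(self) -> pd.DataFrame:
        rows = []
        for subset, accs in zip(self.subsets, self.per_entry_accuracy):
            for entry, acc in accs.items():
                rows.append(
                    {"channels": "+".join(subset), "entry": entry, "accuracy": acc}
                )
        return pd.DataFrame(rows)


def ablation_subsets(
    all_roles: Sequence[str], drop_order: Sequence[str]
) -> list[tuple[str, ...]]:
    """Strictly nested channel subsets: full set, then drop each role of
    ``drop_order`` in turn.  Any resulting empty subset is an error."""
    current = list(all_roles)
    subsets = [tuple(current)]
    for role in drop_order:
        if role not in current:
            raise ValidationError(f"drop_order role {role!r} not present")
        current = [r for r in current if r != role]
        if not current:
            raise ValidationError("drop order exhausts all channels")
        subsets.append(tuple(current))
    return subsets


def ablation_study(
    all_roles: Sequence[str],
    drop_order: Sequence[str],
    run_subset: Callable[[tuple[str, ...]], dict[str, float]],
) -> AblationResult:
    """Retrain-and-evaluate for each nested channel subset.

    ``run_subset`` maps a channel subset to per-test-entry accuracies; it
    is expected to retrain with the same seeds and schedule and evaluate
    on the same test entries (channels are excluded during training and
    testing, not zero-filled at inference).
    """
    result = AblationResult()
    for subset in ablation_subsets(all_roles, drop_order):
        result.subsets.append(subset)
        result.per_entry_accuracy.append(dict(run_subset(subset)))
    return result
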