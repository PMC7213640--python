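"""Patient-aware partitioning, per-patient class balancing, channel subsets.

Test data must come entirely from withheld patients: records of holdout
patients go to test, the remainder is split 80/20 into training and
validation at the cell level, stratified by (patient, class) so that no
validation fold loses a class at desk scale.  Balancing randomly
undersamples each patient's classes to that patient's minimum present
class count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import CellImage, CellRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint cell-id assignment to train/validation/test partitions."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    holdout_patient_ids: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        t, v, s = set(self.train_ids), set(self.validation_ids), set(self.test_ids)
        if t & v or t & s or v & s:
            raise ValidationError("train/validation/test id lists must be disjoint")

    def partition_of(self, cell_id: str) -> str:
        if cell_id in set(self.train_ids):
            return "train"
        if cell_id in set(self.validation_ids):
            return "validation"
        if cell_id in set(self.test_ids):
            return "test"
        return "unassigned"


def assert_patient_disjoint(
    records: Sequence[CellRecord], split: SplitSpec
) -> None:
    """Raise unless no patient contributes to both train/val and test."""
    by_id = {r.cell_id: r.patient_id for r in records}
    trainval = {by_id[c] for c in (*split.train_ids, *split.validation_ids) if c in by_id}
    test = {by_id[c] for c in split.test_ids if c in by_id}
    overlap = trainval & test
    if overlap:
        raise ValidationError(
            f"patients {sorted(overlap)} appear in both train/validation and test"
        )


def partition(
    records: Sequence[CellRecord],
    holdout_patient_ids: Iterable[str],
    val_fraction: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Assign holdout patients' cells to test and split the rest 80/20.

    The 80/20 split is random at the cell level within each
    (patient, class) stratum; deterministic given the seed.
    """
    holdout = frozenset(holdout_patient_ids)
    patients = {r.patient_id for r in records}
    missing = holdout - patients
    if missing:
        raise ValidationError(f"holdout patients not in records: {sorted(missing)}")
    if patients <= holdout:
        raise ValidationError("holdout covers all patients; no training data left")
    rng = np.random.default_rng(seed)
    test_ids = [r.cell_id for r in records if r.patient_id in holdout]
    strata: dict[tuple[str, str | None], list[str]] = {}
    for r in records:
        if r.patient_id in holdout:
            continue
        strata.setdefault((r.patient_id, r.true_class), []).append(r.cell_id)
    train_ids: list[str] = []
    val_ids: list[str] = []
    for key in sorted(strata, key=repr):
        ids = strata[key]
        order = rng.permutation(len(ids))
        n_val = int(round(val_fraction * len(ids)))
        val_ids.extend(ids[i] for i in order[:n_val])
        train_ids.extend(ids[i] for i in order[n_val:])
    spec = SplitSpec(
        train_ids=tuple(train_ids),
        validation_ids=tuple(val_ids),
        test_ids=tuple(test_ids),
        holdout_patient_ids=holdout,
        seed=seed,
    )
    assert_patient_disjoint(records, spec)
    return spec


def balance_per_patient(
    records: Sequence[CellRecord],
    classes: Sequence[str] = ("leukemic", "normal", "other"),
    seed: int = 0,
) -> list[CellRecord]:
    """Undersample each patient's present classes to the patient minimum.

    Sampling is without replacement and deterministic given the seed; a
    patient missing a class contributes only its present classes (logged).
    Never increases any class count.
    """
    rng = np.random.default_rng(seed)
    by_patient: dict[str, dict[str, list[CellRecord]]] = {}
    for r in records:
        if r.true_class is None:
            raise ValidationError(f"record {r.cell_id!r} lacks true_class")
        by_patient.setdefault(r.patient_id, {}).setdefault(r.true_class, []).append(r)
    out: list[CellRecord] = []
    for patient_id in sorted(by_patient):
        groups = by_patient[patient_id]
        present = [c for c in classes if c in groups]
        absent = [c for c in classes if c not in groups]
        if absent:
            logger.info(
                "patient %s lacks classes %s; balancing over %s",
                patient_id, absent, present,
            )
        n_min = min(len(groups[c]) for c in present)
        for c in present:
            pool = groups[c]
            idx = rng.choice(len(pool), size=n_min, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    return out


def select_channels(
    records: Sequence[CellRecord], roles: Sequence[str]
) -> list[CellRecord]:
    """Reduce every record to the given channel-role subset.

    Plane order is preserved (instrument order), never the order of
    ``roles``.  The label-free preset is {BF1, BF2, DF}.
    """
    wanted = set(roles)
    if not wanted:
        raise ValidationError("channel subset must be non-empty")
    out = []
    for r in records:
        available = set(r.image.channel_roles)
        missing = wanted - available
        if missing:
            raise ValidationError(
                f"record {r.cell_id!r} lacks channels {sorted(missing)}"
            )
        keep = [i for i, role in enumerate(r.image.channel_roles) if role in wanted]
        image = CellImage(
            pixels=r.image.pixels[keep],
            channel_roles=tuple(r.image.channel_roles[i] for i in keep),
            pixel_size_um=r.image.pixel_size_um,
        )
        out.append(r.with_image(image))
    return out
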