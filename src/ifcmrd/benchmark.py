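"""End-to-end synthetic benchmark of the residual-disease pipeline.

This is the package's reference protocol: train the small residual CNN on
a synthetic multi-patient cohort, quantify per-sample residual-disease
fractions on held-out synthetic patients, and score the clinical readouts
(sensitivity/specificity at the 25% cutoff, pooled per-cell accuracy)
label-free and with all channels.  Everything is a pure function of one
integer seed.

Problem sizes are desk scale: 4 training patients of 900 cells (balanced
per patient, 80/20 train/validation) and 12 held-out test samples of
2,000 cells whose true leukemic fractions span 2-80%, straddling the 25%
clinical cutoff from both sides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import cnn, mrd, qc, split
from .core import DEFAULT_CHANNEL_ROLES, LABEL_FREE_ROLES, AcquisitionMode, CellRecord
from .preprocess import PreprocessChain
from .synthetic import CohortSpec, SampleSpec, generate_cohort, generate_sample

#: True leukemic percentages of the 12 held-out test samples (6 above and
#: 6 below the 25% treatment-effectiveness cutoff).
TEST_FRACTIONS = (2, 5, 10, 15, 20, 22, 30, 35, 40, 55, 70, 80)

N_TRAIN_PATIENTS = 4
N_TRAIN_CELLS = 900
N_TEST_CELLS = 2000
MRD_CUTOFF = 25.0

#: Training schedule for the benchmark: the clinical pipeline's optimizer,
#: batch size and plateau/early-stop rules, with the epoch cap scaled to
#: desk-size cohorts (the synthetic classes separate within tens of
#: epochs, not hundreds).
BENCH_EPOCHS = 40


def _mix_for(leukemic_pct: float) -> tuple[float, float, float]:
    f = leukemic_pct / 100.0
    rest = 1.0 - f
    return (f, 0.55 * rest, 0.45 * rest)


def training_cohort_spec(seed: int) -> CohortSpec:
    patients = tuple(
        (
            f"TR{i + 1:02d}",
            (SampleSpec("pres", N_TRAIN_CELLS, (1 / 3, 1 / 3, 1 / 3)),),
        )
        for i in range(N_TRAIN_PATIENTS)
    )
    return CohortSpec(patients=patients, seed=seed, mode=AcquisitionMode())


@dataclass
class SampleEval:
    patient_id: str
    timepoint_label: str
    truth_fraction: float
    n_evaluated: int
    true_labels: list[str]
    predictions: dict[str, list[str]] = field(default_factory=dict)  # per model key


@dataclass
class BenchmarkResult:
    """Everything the clinical readouts need, for both channel settings."""

    models: dict[str, cnn.CNNModel]
    histories: dict[str, cnn.TrainHistory]
    samples: list[SampleEval]
    n_train_cells: int

    def mrd_results(self, key: str) -> list[mrd.MRDResult]:
        return [
            mrd.mrd_fraction(
                s.predictions[key], s.patient_id, s.timepoint_label, s.truth_fraction
            )
            for s in self.samples
        ]

    def cutoff_metrics(self, key: str, cutoff: float = MRD_CUTOFF) -> mrd.CutoffMetrics:
        return mrd.cutoff_metrics(self.mrd_results(key), cutoff)

    def pooled_accuracy(self, key: str) -> float:
        pred = [lb for s in self.samples for lb in s.predictions[key]]
        truth = [lb for s in self.samples for lb in s.true_labels]
        return mrd.evaluate_classification(pred, truth)["accuracy"]


def _prepare_training(
    seed: int, channels: Sequence[str], records: list[CellRecord]
) -> tuple[list[CellRecord], split.SplitSpec]:
    kept, _ = qc.filter_in_focus_singlets(records, qc.QCThresholds())
    balanced = split.balance_per_patient(kept, seed=seed + 1)
    selected = split.select_channels(balanced, channels)
    spec = split.partition(selected, holdout_patient_ids=(), seed=seed + 2)
    return selected, spec


def _train_model(
    seed: int,
    channels: Sequence[str],
    records: list[CellRecord],
    chain: PreprocessChain,
    max_epochs: int,
) -> tuple[cnn.CNNModel, cnn.TrainHistory, int]:
    selected, spec = _prepare_training(seed, channels, records)
    model = cnn.build(
        cnn.ArchConfig(preset="small", in_channels=len(channels)), seed=seed + 3
    )
    cfg = cnn.TrainConfig(max_epochs=max_epochs, seed=seed + 4)
    history = cnn.train(model, selected, spec, chain, cfg)
    return model, history, len(spec.train_ids)


def run_benchmark(
    seed: int,
    channel_settings: Optional[dict[str, Sequence[str]]] = None,
    max_epochs: int = BENCH_EPOCHS,
    n_test_cells: int = N_TEST_CELLS,
) -> BenchmarkResult:
    """Run the full protocol once.

    channel_settings maps a model key to its channel subset; the default
    trains both the label-free ({BF1, BF2, DF}) and the all-channel
    models on the same cohort with the same seeds, then evaluates both on
    the same 12 held-out test samples.
    """
    if channel_settings is None:
        channel_settings = {
            "label_free": LABEL_FREE_ROLES,
            "all_channels": DEFAULT_CHANNEL_ROLES,
        }
    seed = int(seed) % (2**31 - 1)
    chain = PreprocessChain()
    cohort = generate_cohort(training_cohort_spec(seed))

    models: dict[str, cnn.CNNModel] = {}
    histories: dict[str, cnn.TrainHistory] = {}
    n_train = 0
    for key, channels in channel_settings.items():
        model, history, n_train = _train_model(
            seed, channels, cohort.records, chain, max_epochs
        )
        models[key] = model
        histories[key] = history

    # stream the held-out test samples: generate, QC, predict, discard pixels
    samples: list[SampleEval] = []
    test_root = np.random.default_rng(np.random.SeedSequence((seed, 9151)))
    for k, pct in enumerate(TEST_FRACTIONS):
        srng = test_root.spawn(1)[0]
        recs = generate_sample(
            patient_id=f"TE{k + 1:02d}",
            timepoint_label="day8",
            n_cells=n_test_cells,
            class_mix=_mix_for(pct),
            contamination={"clump": 0.025, "out_of_focus": 0.025},
            mode=AcquisitionMode(),
            rng=srng,
        )
        clean = [r for r in recs if r.contaminant is None]
        truth_fraction = 100.0 * sum(
            r.true_class == "leukemic" for r in clean
        ) / len(clean)
        kept, _ = qc.filter_in_focus_singlets(recs, qc.QCThresholds())
        ev = SampleEval(
            patient_id=f"TE{k + 1:02d}",
            timepoint_label="day8",
            truth_fraction=truth_fraction,
            n_evaluated=len(kept),
            true_labels=[r.true_class for r in kept],
        )
        for key, channels in channel_settings.items():
            selected = split.select_channels(kept, channels)
            _, labels = cnn.predict(models[key], selected, chain)
            ev.predictions[key] = labels
        samples.append(ev)

    return BenchmarkResult(
        models=models, histories=histories, samples=samples, n_train_cells=n_train
    )


def feature_selection_benchmark(
    seed: int, n_cells: int = 5000
) -> dict[str, float]:
    """Feature-selection stress test with injected collinear columns.

    Extracts the classical feature table from ``n_cells`` synthetic cells
    (two replicate samples per class mix), appends 10 affine transforms of
    existing columns plus small noise, runs the three-stage selection with
    defaults, and brute-forces the full correlation matrix of the retained
    columns.  Returns the maximum off-diagonal |Pearson r| (x100) and the
    retained column count.
    """
    from .features import extract_feature_table, select_features

    seed = int(seed) % (2**31 - 1)
    root = np.random.default_rng(np.random.SeedSequence((seed, 501)))
    half = n_cells // 2
    records = []
    groups: dict[str, tuple[str, str]] = {}
    for rep in ("r1", "r2"):
        recs = generate_sample(
            patient_id=f"FS_{rep}",
            timepoint_label="pres",
            n_cells=half,
            class_mix=(1 / 3, 1 / 3, 1 / 3),
            contamination={},
            mode=AcquisitionMode(),
            rng=root.spawn(1)[0],
        )
        for r in recs:
            groups[r.cell_id] = (r.true_class, rep)
        records.extend(recs)
    table, _ = extract_feature_table(records)

    clone_rng = np.random.default_rng(np.random.SeedSequence((seed, 502)))
    donors = [c for c in table.columns if table[c].std() > 0][:10]
    for i, donor in enumerate(donors):
        scale = float(clone_rng.uniform(0.5, 3.0))
        offset = float(clone_rng.uniform(-5.0, 5.0))
        noise = clone_rng.normal(
            scale=0.01 * max(table[donor].std(), 1e-9), size=len(table)
        )
        table[f"clone_{i:02d}_{donor}"] = scale * table[donor] + offset + noise

    reduced, _ = select_features(table, replicate_groups=groups)
    corr = np.corrcoef(reduced.to_numpy().T)
    np.fill_diagonal(corr, 0.0)
    return {
        "max_abs_corr_pct": float(np.abs(corr).max() * 100.0),
        "n_retained": int(reduced.shape[1]),
        "n_cells": int(len(table)),
    }


def positivity_threshold_scan(
    n_total: int = 500_000, lo: int = 40, hi: int = 60
) -> dict[str, float]:
    """Smallest leukemic percentage that flips the clinical positivity
    call to positive (event-count floor satisfied), over an event grid."""
    from .qc import flow_positivity_call

    for n_leuk in range(lo, hi + 1):
        if flow_positivity_call(n_leuk, n_total) == "positive":
            return {
                "threshold_pct": 100.0 * n_leuk / n_total,
                "n_events_at_threshold": n_leuk,
            }
    raise RuntimeError("no positive call in the scanned grid")


def acceptance_numbers(result: BenchmarkResult) -> dict[str, dict]:
    """The benchmark's headline readouts keyed for reporting."""
    cm = result.cutoff_metrics("label_free")
    n_samples = len(result.samples)
    n_cells = sum(s.n_evaluated for s in result.samples)
    return {
        "mrd_sensitivity_25pct": {"value": cm.sensitivity, "n": n_samples},
        "mrd_specificity_25pct": {"value": cm.specificity, "n": n_samples},
        "labelfree_holdout_accuracy": {
            "value": result.pooled_accuracy("label_free"),
            "n": n_cells,
        },
        "allchannel_holdout_accuracy": {
            "value": result.pooled_accuracy("all_channels"),
            "n": n_cells,
        },
    }
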