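"""Classifier training and inference contracts on a small synthetic run.

The module-scoped trained model (two synthetic patients, label-free
channels, a dozen epochs) backs the accuracy, determinism, embedding and
checkpoint tests without repeating the expensive part.
"""

import numpy as np
import pytest

from ifcmrd import cnn, qc, split
from ifcmrd.core import AcquisitionMode, LABEL_FREE_ROLES, ValidationError
from ifcmrd.preprocess import PreprocessChain
from ifcmrd.synthetic import generate_sample


@pytest.fixture(scope="module")
def training_setup():
    # ~1,500 balanced cells (500/class) across two synthetic patients
    records = []
    for i, pid in enumerate(("TRA", "TRB")):
        rng = np.random.default_rng(100 + i)
        records.extend(
            generate_sample(
                pid, "pres", 780, (1 / 3, 1 / 3, 1 / 3), {}, AcquisitionMode(), rng
            )
        )
    kept, _ = qc.filter_in_focus_singlets(records, qc.QCThresholds())
    balanced = split.balance_per_patient(kept, seed=1)
    selected = split.select_channels(balanced, LABEL_FREE_ROLES)
    spec = split.partition(selected, holdout_patient_ids=(), seed=2)
    return selected, spec


@pytest.fixture(scope="module")
def trained(training_setup):
    # batch 64 rather than 256: at ~1,200 training cells the 30-epoch cap
    # must still give the optimizer enough update steps
    selected, spec = training_setup
    model = cnn.build(cnn.ArchConfig(preset="small", in_channels=3), seed=3)
    cfg = cnn.TrainConfig(max_epochs=30, batch_size=64, seed=4)
    history = cnn.train(model, selected, spec, PreprocessChain(), cfg)
    return model, history, selected, spec


@pytest.fixture(scope="module")
def holdout_records():
    rng = np.random.default_rng(555)
    recs = generate_sample(
        "TEH", "day8", 300, (0.4, 0.3, 0.3), {}, AcquisitionMode(), rng
    )
    kept, _ = qc.filter_in_focus_singlets(recs, qc.QCThresholds())
    return split.select_channels(kept, LABEL_FREE_ROLES)


class TestTraining:
    def test_validation_accuracy_reaches_95pct(self, trained):
        """With the default generator separation the small network learns
        the three classes quickly even under live augmentation."""
        _, history, _, _ = trained
        assert max(history.val_acc) >= 0.95

    def test_history_invariants(self, trained):
        _, history, _, _ = trained
        assert len(history.epoch) <= 30
        lr = history.lr
        assert all(b <= a for a, b in zip(lr, lr[1:]))
        assert history.stop_reason in ("early_stopping", "max_epochs")

    def test_early_stopping_rule_consistent_with_trace(self, trained):
        """Replay the plateau rule offline over the recorded validation
        losses and check the reported stopping epoch."""
        from ifcmrd import nn

        _, history, _, _ = trained
        tracker = nn.PlateauTracker(25, tol=1e-4)
        stop = None
        for epoch, loss in zip(history.epoch, history.val_loss):
            if tracker.update(loss):
                stop = epoch
                break
        if history.stop_reason == "early_stopping":
            assert stop == history.stopped_epoch
        else:
            assert stop is None and history.stopped_epoch == history.epoch[-1]

    def test_missing_class_refused_before_training(self, training_setup):
        selected, spec = training_setup
        two_class = [r for r in selected if r.true_class != "other"]
        ids = {r.cell_id for r in two_class}
        pruned = split.SplitSpec(
            train_ids=tuple(c for c in spec.train_ids if c in ids),
            validation_ids=tuple(c for c in spec.validation_ids if c in ids),
            test_ids=(),
            holdout_patient_ids=spec.holdout_patient_ids,
            seed=0,
        )
        model = cnn.build(cnn.ArchConfig(in_channels=3), seed=0)
        with pytest.raises(ValidationError, match="other"):
            cnn.train(
                model, two_class, pruned, PreprocessChain(),
                cnn.TrainConfig(max_epochs=1),
            )

    def test_patient_disjointness_guard_fires(self, training_setup):
        selected, _ = training_setup
        by_patient = {}
        for r in selected:
            by_patient.setdefault(r.patient_id, []).append(r.cell_id)
        leaky = split.SplitSpec(
            train_ids=tuple(by_patient["TRA"][:50]),
            validation_ids=tuple(by_patient["TRA"][50:60]),
            test_ids=tuple(by_patient["TRA"][60:70]),
            holdout_patient_ids=frozenset(),
            seed=0,
        )
        model = cnn.build(cnn.ArchConfig(in_channels=3), seed=0)
        with pytest.raises(ValidationError, match="both"):
            cnn.train(
                model, selected, leaky, PreprocessChain(), cnn.TrainConfig(max_epochs=1)
            )


class TestInference:
    def test_holdout_accuracy_and_determinism(self, trained, holdout_records):
        model, _, _, _ = trained
        chain = PreprocessChain()
        proba1, labels1 = cnn.predict(model, holdout_records, chain)
        proba2, labels2 = cnn.predict(model, holdout_records, chain)
        assert np.array_equal(proba1, proba2) and labels1 == labels2
        assert np.allclose(proba1.sum(axis=1), 1.0, atol=1e-5)
        truth = [r.true_class for r in holdout_records]
        acc = np.mean([p == t for p, t in zip(labels1, truth)])
        assert acc >= 0.886

    def test_channel_mismatch_names_roles(self, trained, holdout_records):
        model, _, _, _ = trained
        wrong = split.select_channels(holdout_records, ("BF1", "DF"))
        with pytest.raises(ValidationError, match="BF1"):
            cnn.predict(model, wrong, PreprocessChain())

    def test_embeddings_align_and_cluster(self, trained, holdout_records):
        model, _, _, _ = trained
        chain = PreprocessChain()
        emb = cnn.extract_embeddings(model, holdout_records, chain)
        assert emb.shape == (len(holdout_records), model.embedding_width)
        # identical records -> identical rows
        twice = cnn.extract_embeddings(
            model, [holdout_records[0], holdout_records[0]], chain
        )
        assert np.array_equal(twice[0], twice[1])
        # class structure: mean within-class distance < between-class
        truth = np.array([r.true_class for r in holdout_records])
        within, between = [], []
        rng = np.random.default_rng(0)
        idx = rng.choice(len(truth), size=(200, 2))
        for i, j in idx:
            d = float(np.linalg.norm(emb[i] - emb[j]))
            (within if truth[i] == truth[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_checkpoint_roundtrip_preserves_predictions(
        self, trained, holdout_records, tmp_path
    ):
        model, _, _, _ = trained
        chain = PreprocessChain()
        proba, _ = cnn.predict(model, holdout_records[:20], chain)
        path = cnn.save_model(model, tmp_path / "model.npz")
        back = cnn.load_model(path)
        proba2, _ = cnn.predict(back, holdout_records[:20], chain)
        assert np.allclose(proba, proba2, atol=1e-6)
        assert back.channel_roles == model.channel_roles
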