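"""Classical arm: segmentation and feature invariances, three-stage
feature selection with brute-force verification, linear SVM contracts."""

import numpy as np
import pandas as pd
import pytest

from ifcmrd.core import CellImage, ValidationError
from ifcmrd.features import (
    extract_feature_table,
    extract_features,
    fit_linear_classifier,
    segment_object,
    select_features,
)


@pytest.fixture(scope="module")
def disc_image(phenotypes, stained_mode):
    from ifcmrd.synthetic import generate_cell

    return generate_cell(phenotypes["leukemic"], stained_mode, np.random.default_rng(1))


class TestSegmentation:
    def test_blank_image_flagged_unsegmentable(self):
        img = CellImage(
            pixels=np.full((3, 24, 24), 5.0, dtype=np.float32),
            channel_roles=("BF1", "BF2", "DF"),
        )
        mask, ok = segment_object(img)
        assert not ok and not mask.any()

    def test_mask_invariant_under_intensity_rescaling(self, disc_image):
        mask, _ = segment_object(disc_image)
        scaled = CellImage(
            pixels=disc_image.pixels * 3.7, channel_roles=disc_image.channel_roles
        )
        mask2, _ = segment_object(scaled)
        assert np.array_equal(mask, mask2)


class TestExtraction:
    def test_form_factor_of_perfect_disc_near_one(self, disc_image):
        # analytic disc mask: 4*pi*A/P^2 must be within 10% of 1
        yy, xx = np.mgrid[0:48, 0:48]
        mask = (yy - 24.0) ** 2 + (xx - 24.0) ** 2 <= 100.0
        img = CellImage(
            pixels=np.ones((3, 48, 48), dtype=np.float32),
            channel_roles=("BF1", "BF2", "DF"),
        )
        feats = extract_features(img, mask)
        assert abs(feats["shape_form_factor"] - 1.0) < 0.10

    def test_form_factor_of_rendered_cell_is_discoid(self, disc_image):
        mask, _ = segment_object(disc_image)
        feats = extract_features(disc_image, mask)
        assert feats["shape_form_factor"] > 0.6

    def test_intensity_scales_shape_invariant(self, disc_image):
        mask, _ = segment_object(disc_image)
        a = extract_features(disc_image, mask)
        doubled = CellImage(
            pixels=disc_image.pixels * 2.0, channel_roles=disc_image.channel_roles
        )
        b = extract_features(doubled, mask)
        assert b["intensity_BF1_mean"] == pytest.approx(2 * a["intensity_BF1_mean"], rel=1e-6)
        assert b["intensity_DF_median"] == pytest.approx(2 * a["intensity_DF_median"], rel=1e-6)
        for key in ("shape_area", "shape_aspect_ratio", "shape_eccentricity", "shape_solidity"):
            assert b[key] == a[key]

    def test_identical_images_identical_vectors(self, disc_image):
        mask, _ = segment_object(disc_image)
        a = extract_features(disc_image, mask)
        b = extract_features(disc_image, mask)
        assert a == b

    def test_all_features_finite_across_sample(self, small_sample):
        table, flagged = extract_feature_table(small_sample[:20])
        assert not flagged
        assert np.isfinite(table.to_numpy()).all()
        assert table.columns.is_unique
        assert 60 <= table.shape[1] <= 130


def _random_table(rng, n=300, p=20):
    data = rng.normal(size=(n, p))
    cols = [f"f{i:02d}" for i in range(p)]
    return pd.DataFrame(data, columns=cols, index=[f"c{i}" for i in range(n)])


class TestSelection:
    def test_constant_column_dropped_by_nzv(self):
        rng = np.random.default_rng(0)
        table = _random_table(rng)
        table["const"] = 3.14
        reduced, report = select_features(table)
        assert "const" not in reduced.columns
        assert "const" in report.by_rule("near_zero_variance")

    def test_duplicated_column_pruned_to_one(self):
        rng = np.random.default_rng(1)
        table = _random_table(rng)
        table["dup"] = table["f00"]
        reduced, report = select_features(table)
        survivors = {"f00", "dup"} & set(reduced.columns)
        assert len(survivors) == 1
        assert report.by_rule("redundancy")

    def test_injected_collinear_pairs_brute_force_check(self):
        rng = np.random.default_rng(2)
        table = _random_table(rng, n=400, p=50)
        for i in range(10):
            noise = rng.normal(scale=0.01, size=len(table))
            table[f"clone{i}"] = 2.0 * table[f"f{i:02d}"] + 1.0 + noise
        reduced, _ = select_features(table)
        corr = np.corrcoef(reduced.to_numpy().T)
        np.fill_diagonal(corr, 0.0)
        assert np.abs(corr).max() <= 0.95

    def test_selection_is_idempotent(self):
        rng = np.random.default_rng(3)
        table = _random_table(rng)
        table["dup"] = table["f01"] + rng.normal(scale=1e-3, size=len(table))
        reduced, _ = select_features(table)
        reduced2, report2 = select_features(reduced)
        assert list(reduced2.columns) == list(reduced.columns)
        assert report2.dropped.empty

    def test_replicate_filter_drops_unstable_feature(self):
        rng = np.random.default_rng(4)
        groups = {}
        rows = []
        idx = []
        for rep in ("r1", "r2"):
            for grp in range(6):
                for k in range(10):
                    cid = f"{rep}_{grp}_{k}"
                    idx.append(cid)
                    groups[cid] = (f"g{grp}", rep)
                    rows.append(
                        {
                            "stable": grp + rng.normal(scale=0.1),
                            "unstable": rng.normal(),
                        }
                    )
        table = pd.DataFrame(rows, index=idx)
        reduced, report = select_features(table, replicate_groups=groups)
        assert "stable" in reduced.columns
        assert "unstable" in report.by_rule("replicate_correlation")

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            select_features(pd.DataFrame())


class TestLinearClassifier:
    def test_separable_data_perfect_training_accuracy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(loc=0.0, size=(60, 5))
        b = rng.normal(loc=8.0, size=(60, 5))
        table = pd.DataFrame(np.vstack([a, b]))
        table.columns = [f"f{i}" for i in range(5)]
        labels = ["neg"] * 60 + ["pos"] * 60
        clf = fit_linear_classifier(table, labels, search_budget=8, seed=0)
        assert (clf.predict(table) == np.asarray(labels)).mean() == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(300, 8)))
        table.columns = [f"f{i}" for i in range(8)]
        labels = list(rng.permutation(["a", "b"] * 150))
        clf = fit_linear_classifier(table, labels, search_budget=5, seed=1)
        # chance is 0.5; allow binomial noise on the validation fold
        assert 0.3 <= clf.validation_accuracy <= 0.7

    def test_single_class_rejected(self):
        table = pd.DataFrame(np.zeros((10, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            fit_linear_classifier(table, ["x"] * 10)

    def test_leave_one_patient_out_structure(self):
        from ifcmrd.features import leave_one_patient_out

        rng = np.random.default_rng(7)
        rows, labels, patients = [], {}, {}
        for p in ("PA", "PB", "PC"):
            for cls, loc in (("neg", 0.0), ("pos", 6.0)):
                for k in range(25):
                    cid = f"{p}_{cls}_{k}"
                    rows.append((cid, rng.normal(loc=loc, size=4)))
                    labels[cid] = cls
                    patients[cid] = p
        table = pd.DataFrame(
            [r[1] for r in rows], index=[r[0] for r in rows],
            columns=[f"f{i}" for i in range(4)],
        )
        out = leave_one_patient_out(table, labels, patients, search_budget=4, seed=0)
        assert list(out["patient"]) == ["PA", "PB", "PC"]
        assert (out["n_cells"] == 50).all()
        # patients share the class structure, so held-out accuracy is high
        assert (out["accuracy"] >= 0.95).all()
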