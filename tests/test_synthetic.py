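"""Generator contracts: determinism, acquisition modes, cohort structure,
and the label-free separability guard."""

import numpy as np
import pytest
from scipy.stats import binom

from ifcmrd.core import AcquisitionMode, FLUOR_ROLES, ValidationError
from ifcmrd.synthetic import (
    CohortSpec,
    PhenotypeSpec,
    SampleSpec,
    default_phenotypes,
    generate_cell,
    generate_cohort,
    generate_sample,
)
from ifcmrd.qc import brightfield_mask


def test_generate_cell_is_deterministic(phenotypes, stained_mode):
    a = generate_cell(phenotypes["leukemic"], stained_mode, np.random.default_rng(7))
    b = generate_cell(phenotypes["leukemic"], stained_mode, np.random.default_rng(7))
    assert np.array_equal(a.pixels, b.pixels)


def test_stained_cell_has_marker_signal_over_background(phenotypes, stained_mode):
    """Inside-cell CD10 intensity exceeds background by about the generating
    amplitude (log-normal draw, so compare against mean minus 2 log-sd)."""
    spec = phenotypes["leukemic"]
    img = generate_cell(spec, stained_mode, np.random.default_rng(7))
    mask = brightfield_mask(img)
    cd10 = img.channel("CD10")
    border = np.concatenate([cd10[:3].ravel(), cd10[-3:].ravel()])
    mean_amp, log_sd = spec.marker_means["CD10"]
    floor = mean_amp * np.exp(-2 * log_sd)
    assert cd10[mask].mean() - border.mean() >= floor


@pytest.mark.parametrize("stained,laser_on", [(False, True), (True, False), (False, False)])
def test_fluorescence_channels_are_noise_only_without_stain_and_laser(
    phenotypes, stained, laser_on
):
    from ifcmrd.synthetic import FLUOR_DETECTOR_MEAN, FLUOR_DETECTOR_SD

    mode = AcquisitionMode(stained=stained, laser_on=laser_on)
    img = generate_cell(phenotypes["leukemic"], mode, np.random.default_rng(3))
    for role in FLUOR_ROLES:
        plane = img.channel(role)
        se = FLUOR_DETECTOR_SD / np.sqrt(plane.size)
        assert abs(plane.mean() - FLUOR_DETECTOR_MEAN) < 3 * se + 0.05


def test_brightfield_darkfield_identical_across_modes(phenotypes):
    """With zero bleed-through the label-free channels must be bit-identical
    across all four acquisition arms for the same seed."""
    images = [
        generate_cell(
            phenotypes["other"],
            AcquisitionMode(stained=s, laser_on=l, bleedthrough_coeff=0.0),
            np.random.default_rng(11),
        )
        for s in (True, False)
        for l in (True, False)
    ]
    for role in ("BF1", "BF2", "DF"):
        ref = images[0].channel(role)
        for img in images[1:]:
            assert np.array_equal(ref, img.channel(role))


def test_bleedthrough_raises_brightfield_when_stained(phenotypes):
    base = generate_cell(
        phenotypes["leukemic"],
        AcquisitionMode(bleedthrough_coeff=0.0),
        np.random.default_rng(5),
    )
    bled = generate_cell(
        phenotypes["leukemic"],
        AcquisitionMode(bleedthrough_coeff=0.1),
        np.random.default_rng(5),
    )
    assert bled.channel("BF1").mean() > base.channel("BF1").mean()


def test_invalid_phenotype_fields_are_rejected(phenotypes):
    spec = phenotypes["normal"]
    with pytest.raises(ValidationError, match="cell_radius_px"):
        PhenotypeSpec(
            class_label="normal",
            cell_radius_px=(2.0, 0.5),
            nucleus_to_cell_ratio=spec.nucleus_to_cell_ratio,
            texture_grain_px=spec.texture_grain_px,
            darkfield_granularity=spec.darkfield_granularity,
            marker_means=dict(spec.marker_means),
            brightfield_contrast=spec.brightfield_contrast,
        )


class TestGenerateSample:
    def test_class_counts_within_binomial_bounds(self, mixed_sample):
        clean = [r for r in mixed_sample if r.contaminant is None]
        n = len(clean)
        for cls, p in zip(("leukemic", "normal", "other"), (1 / 3, 1 / 3, 1 / 3)):
            count = sum(r.true_class == cls for r in clean)
            lo, hi = binom.ppf([0.005, 0.995], n, p)
            assert lo <= count <= hi

    def test_contaminant_counts_and_flags(self, mixed_sample):
        n_clean = sum(r.contaminant is None for r in mixed_sample)
        assert n_clean == 2000
        assert sum(r.contaminant == "clump" for r in mixed_sample) == 100
        assert sum(r.contaminant == "out_of_focus" for r in mixed_sample) == 100

    def test_zero_contamination_and_pure_mix(self, stained_mode):
        recs = generate_sample(
            "P", "t", 50, (1, 0, 0), {}, stained_mode, np.random.default_rng(0)
        )
        assert all(r.contaminant is None for r in recs)
        assert all(r.true_class == "leukemic" for r in recs)

    def test_rejects_empty_sample(self, stained_mode):
        with pytest.raises(ValidationError):
            generate_sample(
                "P", "t", 0, (1, 0, 0), {}, stained_mode, np.random.default_rng(0)
            )


class TestGenerateCohort:
    def _spec(self, seed=0):
        return CohortSpec(
            patients=tuple(
                (f"P{i}", (SampleSpec("pres", 120, (0.4, 0.3, 0.3)),))
                for i in range(6)
            ),
            holdout_patient_ids=frozenset({"P4", "P5"}),
            seed=seed,
        )

    def test_holdout_partition(self):
        cohort = generate_cohort(self._spec())
        assert {r.patient_id for r in cohort.train_pool} == {"P0", "P1", "P2", "P3"}
        assert {r.patient_id for r in cohort.holdout_pool} == {"P4", "P5"}

    def test_same_seed_reproduces_cohort(self):
        a = generate_cohort(self._spec(3))
        b = generate_cohort(self._spec(3))
        assert [r.cell_id for r in a.records] == [r.cell_id for r in b.records]
        assert all(
            np.array_equal(x.image.pixels, y.image.pixels)
            for x, y in zip(a.records[:20], b.records[:20])
        )

    def test_truth_fraction_within_binomial_bounds(self, stained_mode):
        spec = CohortSpec(
            patients=(("P0", (SampleSpec("pres", 5000, (0.4, 0.35, 0.25)),)),),
            contamination={},
            seed=1,
        )
        cohort = generate_cohort(spec)
        lo, hi = binom.ppf([0.005, 0.995], 5000, 0.4) / 5000 * 100
        assert lo <= cohort.samples[0].truth_leukemic_fraction <= hi

    def test_duplicate_patient_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CohortSpec(
                patients=(
                    ("P0", (SampleSpec("a", 10, (1, 0, 0)),)),
                    ("P0", (SampleSpec("b", 10, (1, 0, 0)),)),
                ),
            )


def test_label_free_separability_guard(mixed_sample):
    """Nearest-centroid on (object radius, dark-field high-pixel count) must
    reach >=95% on clean cells — guards against a degenerate generator."""
    clean = [r for r in mixed_sample if r.contaminant is None][:1000]
    feats, labels = [], []
    for r in clean:
        mask = brightfield_mask(r.image)
        radius = np.sqrt(mask.sum() / np.pi)
        df = r.image.channel("DF")
        speckle = np.count_nonzero(df[mask] > 60)
        feats.append((radius, speckle))
        labels.append(r.true_class)
    x = np.asarray(feats)
    y = np.asarray(labels)
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    centroids = {c: x[y == c].mean(axis=0) for c in np.unique(y)}
    classes = sorted(centroids)
    dists = np.stack([np.linalg.norm(x - centroids[c], axis=1) for c in classes])
    pred = np.asarray(classes)[dists.argmin(axis=0)]
    assert (pred == y).mean() >= 0.95
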