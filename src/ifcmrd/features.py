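"""Classical image-analysis arm: segmentation, hand-crafted features,
Cytominer-style feature selection, and a linear max-margin classifier.

The feature families mirror a standard high-content pipeline: per-channel
intensity statistics inside the object mask, size/shape descriptors,
grey-level co-occurrence texture, gradient energy, and cross-channel
intensity correlations.  A compact native extractor built on scikit-image
replaces the original high-content software; exact parity with it is a
non-goal — the families and the downstream selection logic are what the
comparison arm needs.

Feature selection applies three sequential filters: (1) near-zero
variance, (2) poor correlation across replicate groups, (3) greedy
redundancy pruning so that no retained pair has |Pearson r| above the
cutoff (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import perimeter_crofton

from .core import CellImage, CellRecord, ValidationError
from .qc import brightfield_mask, _aspect_ratio

_TEXTURE_CHANNELS = ("BF1", "DF")
_CORR_CHANNELS = ("BF1", "BF2", "DF", "CD10", "CD19", "CD45", "DAPI")


def segment_object(image: CellImage) -> tuple[np.ndarray, bool]:
    """Binary object mask on BF1 (global threshold, holes filled, largest
    component).  Returns (mask, ok); ok=False flags an unsegmentable
    record instead of raising.  The mask is invariant to rescaling all
    intensities by a constant factor."""
    mask = brightfield_mask(image)
    return mask, bool(mask.any())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def extract_features(image: CellImage, mask: np.ndarray) -> dict[str, float]:
    """~100 named features for one cell; all values finite.

    Intensity statistics are computed inside the mask per channel; shape
    from the mask alone (so intensity rescaling leaves them unchanged);
    texture from 8-level co-occurrence matrices at 1-2 px offsets on the
    bright-field and dark-field channels.
    """
    if mask.shape != image.pixels.shape[1:]:
        raise ValidationError("mask shape does not match image planes")
    if not mask.any():
        raise ValidationError("mask is empty; segment_object flagged this record")
    feats: dict[str, float] = {}

    for i, role in enumerate(image.channel_roles):
        vals = np.asarray(image.pixels[i][mask], dtype=np.float64)
        feats[f"intensity_{role}_mean"] = float(vals.mean())
        feats[f"intensity_{role}_median"] = float(np.median(vals))
        feats[f"intensity_{role}_sd"] = float(vals.std())
        feats[f"intensity_{role}_mad"] = float(median_abs_deviation(vals))
        q25, q75 = np.percentile(vals, [25, 75])
        feats[f"intensity_{role}_q25"] = float(q25)
        feats[f"intensity_{role}_q75"] = float(q75)

    area = float(mask.sum())
    # Crofton estimator: far less rasterization bias than edge counting
    perim = max(float(perimeter_crofton(mask, directions=4)), 1.0)
    feats["shape_area"] = area
    feats["shape_perimeter"] = perim
    feats["shape_form_factor"] = 4.0 * np.pi * area / perim**2
    feats["shape_aspect_ratio"] = _aspect_ratio(mask)
    ys, xs = np.nonzero(mask)
    cov = np.cov(np.stack([ys - ys.mean(), xs - xs.mean()]))
    evals = np.clip(np.linalg.eigvalsh(cov), 0, None)
    major, minor = float(evals[-1]), float(evals[0])
    feats["shape_eccentricity"] = (
        float(np.sqrt(1.0 - minor / major)) if major > 1e-12 else 0.0
    )
    hull_area = _convex_hull_area(mask)
    feats["shape_solidity"] = area / hull_area if hull_area > 0 else 1.0

    for role in _TEXTURE_CHANNELS:
        if not image.has_role(role):
            continue
        plane = np.asarray(image.channel(role), dtype=np.float64)
        lo, hi = plane.min(), plane.max()
        levels = 8
        quant = (
            np.clip(((plane - lo) / (hi - lo + 1e-12) * levels).astype(int), 0, levels - 1)
        ).astype(np.uint8)
        for offset in (1, 2):
            glcm = graycomatrix(
                quant, [offset], [0, np.pi / 2], levels=levels, symmetric=True,
                normed=True,
            )
            feats[f"texture_{role}_contrast_{offset}px"] = float(
                graycoprops(glcm, "contrast").mean()
            )
            feats[f"texture_{role}_homogeneity_{offset}px"] = float(
                graycoprops(glcm, "homogeneity").mean()
            )
            p = glcm.mean(axis=3)[:, :, 0]
            feats[f"texture_{role}_entropy_{offset}px"] = _entropy(p.ravel())

    for role in ("BF1", "BF2"):
        if not image.has_role(role):
            continue
        plane = np.asarray(image.channel(role), dtype=np.float64)
        gy, gx = np.gradient(plane)
        feats[f"gradient_{role}_rms"] = float(np.sqrt((gy**2 + gx**2)[mask].mean()))

    present = [r for r in _CORR_CHANNELS if image.has_role(r)]
    for a_i, role_a in enumerate(present):
        va = image.channel(role_a)[mask].astype(np.float64)
        for role_b in present[a_i + 1 :]:
            vb = image.channel(role_b)[mask].astype(np.float64)
            sa, sb = va.std(), vb.std()
            if sa < 1e-12 or sb < 1e-12:
                r = 0.0
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            feats[f"correlation_{role_a}_{role_b}"] = r

    bad = {k: v for k, v in feats.items() if not np.isfinite(v)}
    if bad:
        raise ValidationError(f"non-finite features: {sorted(bad)}")
    return feats


def _convex_hull_area(mask: np.ndarray) -> float:
    from skimage.morphology import convex_hull_image

    return float(convex_hull_image(mask).sum())


def extract_feature_table(
    records: Sequence[CellRecord],
) -> tuple[pd.DataFrame, list[str]]:
    """FeatureTable (rows=cell_id) plus the ids flagged unsegmentable."""
    rows, index, flagged = [], [], []
    for rec in records:
        mask, ok = segment_object(rec.image)
        if not ok:
            flagged.append(rec.cell_id)
            continue
        rows.append(extract_features(rec.image, mask))
        index.append(rec.cell_id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="cell_id"))
    return table, flagged


# ---------------------------------------------------------------------------
# Feature selection


NZV_THRESHOLD = 1e-4       # variance / squared range floor
REPLICATE_CORR_FLOOR = 0.5  # across-replicate correlation of median profiles


@dataclass
class SelectionReport:
    dropped: pd.DataFrame  # columns: feature, rule, statistic

    def by_rule(self, rule: str) -> list[str]:
        d = self.dropped
        return list(d.loc[d["rule"] == rule, "feature"])


def _replicate_correlations(
    table: pd.DataFrame, replicate_groups: Mapping[str, tuple[str, str]]
) -> pd.Series:
    """Per-feature correlation of group-median profiles across replicates.

    ``replicate_groups`` maps cell_id -> (group, replicate).  For each
    replicate, build the vector of per-group medians; a feature's score is
    the mean Pearson correlation over replicate pairs.
    """
    meta = pd.DataFrame.from_dict(
        dict(replicate_groups), orient="index", columns=["group", "replicate"]
    )
    joined = table.join(meta, how="inner")
    profiles = joined.groupby(["replicate", "group"]).median()
    replicates = profiles.index.get_level_values(0).unique()
    if len(replicates) < 2:
        raise ValidationError("need >= 2 replicates for replicate filtering")
    scores = {}
    for feat in table.columns:
        wide = profiles[feat].unstack(level=0)  # groups x replicates
        corr = wide.corr().to_numpy()
        upper = corr[np.triu_indices_from(corr, k=1)]
        upper = upper[np.isfinite(upper)]
        scores[feat] = float(upper.mean()) if upper.size else 0.0
    return pd.Series(scores)


def select_features(
    table: pd.DataFrame,
    replicate_groups: Optional[Mapping[str, tuple[str, str]]] = None,
    nzv_threshold: float = NZV_THRESHOLD,
    corr_cutoff: float = 0.95,
    replicate_corr_floor: float = REPLICATE_CORR_FLOOR,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Three-stage pruning; idempotent, order (1) nzv -> (2) replicate ->
    (3) redundancy.  After stage 3 no retained pair has |Pearson r| above
    ``corr_cutoff``; within each mutually-correlated group the feature
    with the best replicate correlation survives (ties: first by name).
    """
    if table.empty:
        raise ValidationError("feature table is empty")
    dropped: list[dict] = []
    work = table.copy()

    # (1) near-zero variance: variance relative to squared value range
    rng_sq = (work.max() - work.min()) ** 2
    ratio = work.var(ddof=0) / rng_sq.replace(0.0, np.nan)
    ratio = ratio.fillna(0.0)
    for feat in work.columns[ratio < nzv_threshold]:
        dropped.append(
            {"feature": feat, "rule": "near_zero_variance", "statistic": ratio[feat]}
        )
    work = work.drop(columns=[d["feature"] for d in dropped])

    # (2) poor correlation across replicates
    if replicate_groups is not None and not work.empty:
        rep = _replicate_correlations(work, replicate_groups)
        low = [f for f in work.columns if rep[f] < replicate_corr_floor]
        for feat in low:
            dropped.append(
                {"feature": feat, "rule": "replicate_correlation", "statistic": rep[feat]}
            )
        work = work.drop(columns=low)
        rep_scores = rep
    else:
        rep_scores = pd.Series(1.0, index=work.columns)

    # (3) redundancy pruning over the |r| > cutoff graph
    if work.shape[1] > 1:
        corr = work.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        cols = list(work.columns)
        adjacency = corr > corr_cutoff
        seen: set[int] = set()
        for start in range(len(cols)):
            if start in seen or not adjacency[start].any():
                seen.add(start)
                continue
            # connected component of mutually correlated features
            comp, stack = set(), [start]
            while stack:
                node = stack.pop()
                if node in comp:
                    continue
                comp.add(node)
                stack.extend(int(j) for j in np.nonzero(adjacency[node])[0] if j not in comp)
            seen |= comp
            names = sorted(cols[i] for i in comp)
            best = max(rep_scores.get(f, 1.0) for f in names)
            # highest replicate correlation wins; ties -> first by name
            keep = next(f for f in names if rep_scores.get(f, 1.0) == best)
            for f in names:
                if f != keep:
                    dropped.append(
                        {
                            "feature": f,
                            "rule": "redundancy",
                            "statistic": rep_scores.get(f, 1.0),
                        }
                    )
        work = work.drop(columns=[d["feature"] for d in dropped if d["rule"] == "redundancy"])

    report = SelectionReport(
        dropped=pd.DataFrame(dropped, columns=["feature", "rule", "statistic"])
    )
    return work, report


# ---------------------------------------------------------------------------
# Linear max-margin classifier


@dataclass
class LinearClassifier:
    pipeline: object  # sklearn Pipeline (scaler + LinearSVC)
    C: float
    validation_accuracy: float
    classes: tuple[str, ...]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(table.to_numpy())

    def decision_scores(self, table: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(table.to_numpy())


def leave_one_patient_out(
    table: pd.DataFrame,
    labels: Mapping[str, str],
    patients: Mapping[str, str],
    search_budget: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-patient-out evaluation of the linear classifier.

    ``labels`` and ``patients`` map cell_id -> class / patient.  For each
    patient, fit on all other patients' cells and score on the held-out
    patient.  Returns a frame (patient, n_cells, accuracy); deterministic
    given the seed.
    """
    ids = list(table.index)
    pat = pd.Series({i: patients[i] for i in ids})
    y = pd.Series({i: labels[i] for i in ids})
    rows = []
    for patient in sorted(pat.unique()):
        held = pat == patient
        if held.all():
            raise ValidationError("need at least two patients")
        clf = fit_linear_classifier(
            table.loc[~held], y[~held].to_list(), search_budget, seed
        )
        pred = clf.predict(table.loc[held])
        acc = float((pred == y[held].to_numpy()).mean())
        rows.append(
            {"patient": patient, "n_cells": int(held.sum()), "accuracy": acc}
        )
    return pd.DataFrame(rows)


def fit_linear_classifier(
    table: pd.DataFrame,
    labels: Sequence[str],
    search_budget: int = 20,
    seed: int = 0,
) -> LinearClassifier:
    """Standardize (train statistics), fit a linear SVM, and pick the
    regularization strength C by randomized log-uniform search scored on a
    held-out validation split.  Deterministic given the seed."""
    from sklearn.model_selection import train_test_split
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need >= 2 classes to fit a classifier")
    x = table.to_numpy()
    rng = np.random.default_rng(seed)
    x_tr, x_va, y_tr, y_va = train_test_split(
        x, y, test_size=0.2, random_state=seed, stratify=y
    )
    best = (-np.inf, 1.0, None)
    for _ in range(search_budget):
        c = float(10 ** rng.uniform(-3, 3))
        pipe = make_pipeline(
            StandardScaler(), LinearSVC(C=c, random_state=seed, max_iter=5000)
        )
        pipe.fit(x_tr, y_tr)
        acc = float((pipe.predict(x_va) == y_va).mean())
        if acc > best[0]:
            best = (acc, c, pipe)
    acc, c, pipe = best
    # refit on all data at the chosen C
    final = make_pipeline(
        StandardScaler(), LinearSVC(C=c, random_state=seed, max_iter=5000)
    )
    final.fit(x, y)
    return LinearClassifier(
        pipeline=final, C=c, validation_accuracy=acc,
        classes=tuple(sorted(np.unique(y))),
    )
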