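"""Event quality control and the fluorescence sequential-gating oracle.

QC reproduces the instrument-side exclusion of clumped and out-of-focus
events using aspect ratio, object area, and the gradient root-mean-square
focus score on the first bright-field channel.  Sequential gating
reproduces the manual marker-based decision tree that defines ground
truth: DAPI- events are red cells/debris; DAPI+ events that are CD19- or
have high side scatter (dark-field surrogate) are "other"; CD19+ CD10+
cells are leukemic blasts regardless of CD34/CD45 (the immunophenotype is
CD34+/- and CD45+/-); CD19+ CD10- CD34- CD45+ cells are normal B
lymphocytes; remaining CD19+ cells fall back to "other".

No numeric QC cutoffs are published for the instrument; the defaults here
were calibrated once on the synthetic generator's default phenotypes and
are plain documented constants, overridable everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import CellImage, CellRecord, ValidationError

#: Default DAPI positivity cutoff (mask-mean intensity), shared by QC's
#: nucleated-cell check and the gate tree.
DEFAULT_DAPI_CUTOFF = 40.0


@dataclass(frozen=True)
class QCThresholds:
    """Singlet/in-focus acceptance box.

    Defaults calibrated on the synthetic generator: clean cells span areas
    ~80-800 px^2 with aspect ratio >= ~0.8; doublets fall below aspect
    0.76, defocused events below the gradient-RMS floor of 6.5.
    """

    min_area_px: float = 60.0
    max_area_px: float = 1000.0
    min_aspect_ratio: float = 0.76
    min_gradient_rms: float = 6.5

    def __post_init__(self) -> None:
        if not self.min_area_px < self.max_area_px:
            raise ValidationError("min_area_px must be < max_area_px")
        if not (0 < self.min_aspect_ratio <= 1):
            raise ValidationError("min_aspect_ratio must be in (0, 1]")
        if self.min_gradient_rms < 0:
            raise ValidationError("min_gradient_rms must be >= 0")

    @classmethod
    def permissive(cls) -> "QCThresholds":
        return cls(min_area_px=0.0 + 1e-9, max_area_px=np.inf,
                   min_aspect_ratio=1e-9, min_gradient_rms=0.0)


@dataclass(frozen=True)
class GateConfig:
    """Marker positivity cutoffs (mask-mean intensities) for the gate tree.

    Defaults sit at the geometric midpoint of the generator's negative and
    positive log-normal populations (>=10x apart), making the gate a
    >=99%-faithful truth oracle on default synthetic data.
    """

    cd19: float = 65.0
    cd10: float = 65.0
    cd34: float = 50.0
    cd45: float = 95.0
    dapi: float = DEFAULT_DAPI_CUTOFF
    darkfield_high: float = 46.0

    def __post_init__(self) -> None:
        for name in ("cd19", "cd10", "cd34", "cd45", "dapi", "darkfield_high"):
            if getattr(self, name) < 0:
                raise ValidationError(f"gate cutoff {name} must be >= 0")


# ---------------------------------------------------------------------------
# Segmentation + metrics


def brightfield_mask(image: CellImage) -> np.ndarray:
    """Object mask from BF1: Otsu-style global threshold on the absolute
    deviation from the median intensity (captures both the dark interior
    and the bright rim), holes filled, largest connected component kept.

    Returns an all-false mask when no object is found.
    """
    bf = np.asarray(image.channel("BF1"), dtype=np.float64)
    dev = ndimage.gaussian_filter(np.abs(bf - np.median(bf)), 1.0)
    if dev.max() <= 1e-12:
        return np.zeros(bf.shape, dtype=bool)
    try:
        thr = threshold_otsu(dev)
    except ValueError:
        return np.zeros(bf.shape, dtype=bool)
    # Otsu alone lands mid-way up the cell's contrast range and clips the
    # low-deviation band just inside the rim; cap it at a robust multiple
    # of the background-noise floor so the mask reaches the cell boundary.
    thr = min(thr, 3.2 * np.median(dev))
    raw = ndimage.binary_closing(dev > thr, structure=np.ones((3, 3)))
    filled = ndimage.binary_fill_holes(raw)
    labels, n = ndimage.label(filled)
    if n == 0:
        return np.zeros(bf.shape, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def _aspect_ratio(mask: np.ndarray) -> float:
    """Minor/major axis ratio from the mask's second central moments."""
    ys, xs = np.nonzero(mask)
    if len(ys) < 2:
        return 1.0
    y = ys - ys.mean()
    x = xs - xs.mean()
    cov = np.cov(np.stack([y, x]))
    evals = np.linalg.eigvalsh(cov)
    major = max(float(evals[-1]), 1e-12)
    minor = max(float(evals[0]), 0.0)
    return float(np.sqrt(minor / major))


def compute_qc_metrics(image: CellImage) -> dict:
    """Area, aspect ratio, BF1 focus score, and per-channel mask means.

    gradient_rms is the root-mean-square first-difference gradient
    magnitude of BF1 over the cell region.  An empty mask yields area 0
    and the record is flagged via ``"empty_mask": True``.
    """
    mask = brightfield_mask(image)
    area = int(mask.sum())
    metrics: dict = {"area_px": area, "empty_mask": area == 0}
    if area == 0:
        metrics.update({"aspect_ratio": 0.0, "gradient_rms": 0.0})
        metrics["channel_means"] = {
            role: float(np.mean(image.pixels[i]))
            for i, role in enumerate(image.channel_roles)
        }
        return metrics
    metrics["aspect_ratio"] = _aspect_ratio(mask)
    bf = np.asarray(image.channel("BF1"), dtype=np.float64)
    gy, gx = np.gradient(bf)
    gmag2 = gy**2 + gx**2
    metrics["gradient_rms"] = float(np.sqrt(gmag2[mask].mean()))
    metrics["channel_means"] = {
        role: float(image.pixels[i][mask].mean())
        for i, role in enumerate(image.channel_roles)
    }
    return metrics


def _metrics_for(record: CellRecord) -> dict:
    if record.qc is None or "channel_means" not in record.qc:
        record.qc = compute_qc_metrics(record.image)
    return record.qc


# ---------------------------------------------------------------------------
# Filtering and gating


def filter_in_focus_singlets(
    records: Sequence[CellRecord],
    thresholds: QCThresholds,
    dapi_cutoff: float = DEFAULT_DAPI_CUTOFF,
) -> tuple[list[CellRecord], list[tuple[CellRecord, str]]]:
    """Partition records into kept in-focus singlets and rejects.

    Tests run in order (area, aspect_ratio, focus, dapi); a rejection
    records the first failed test.  The DAPI nucleation test applies only
    when fluorescence content is present (stained and laser-on).
    kept + rejected is always the full input; the filter is idempotent.
    """
    kept: list[CellRecord] = []
    rejected: list[tuple[CellRecord, str]] = []
    for rec in records:
        m = _metrics_for(rec)
        if not (thresholds.min_area_px <= m["area_px"] <= thresholds.max_area_px):
            rejected.append((rec, "area"))
        elif m["aspect_ratio"] < thresholds.min_aspect_ratio:
            rejected.append((rec, "aspect_ratio"))
        elif m["gradient_rms"] < thresholds.min_gradient_rms:
            rejected.append((rec, "focus"))
        elif (
            rec.acquisition.fluorescence_active
            and m["channel_means"].get("DAPI", np.inf) < dapi_cutoff
        ):
            rejected.append((rec, "dapi"))
        else:
            kept.append(rec)
    return kept, rejected


def sequential_gate(
    records: Sequence[CellRecord],
    config: GateConfig = GateConfig(),
) -> list[str]:
    """Marker-based class label per record: leukemic/normal/other/debris.

    Deterministic and order-independent.  Requires fluorescence content;
    unstained or laser-off records cannot be gated (use true_class or
    model predictions for those acquisitions instead).
    """
    labels = []
    for rec in records:
        if not rec.acquisition.fluorescence_active:
            raise ValidationError(
                "sequential_gate needs stained, laser-on records; for "
                "label-free acquisitions use true_class or model predictions"
            )
        means = _metrics_for(rec)["channel_means"]
        dapi = means.get("DAPI", 0.0)
        cd19 = means.get("CD19", 0.0)
        cd10 = means.get("CD10", 0.0)
        cd34 = means.get("CD34", 0.0)
        cd45 = means.get("CD45", 0.0)
        df = means.get("DF", 0.0)
        if dapi < config.dapi:
            labels.append("debris")
        elif cd19 < config.cd19 or df > config.darkfield_high:
            labels.append("other")
        elif cd10 >= config.cd10:
            labels.append("leukemic")  # CD34/CD45 not decisive
        elif cd34 < config.cd34 and cd45 >= config.cd45:
            labels.append("normal")
        else:
            labels.append("other")
    return labels


def flow_positivity_call(n_leukemic: int, n_total: int) -> str:
    """Clinical sample-positivity rule: positive iff the leukemic fraction
    is at least 0.01% of nucleated cells AND at least 50 events cluster."""
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    if n_leukemic < 0 or n_leukemic > n_total:
        raise ValidationError("need 0 <= n_leukemic <= n_total")
    positive = (n_leukemic / n_total >= 0.0001) and (n_leukemic >= 50)
    return "positive" if positive else "negative"
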