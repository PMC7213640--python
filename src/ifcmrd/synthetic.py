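"""Synthetic single-cell image generator.

Emulates the statistical structure of imaging-flow-cytometry data from
childhood B-lineage acute lymphoblastic leukemia (ALL) bone-marrow samples:
three morphologically distinct cell classes (leukemic blasts, normal B
lymphocytes, "other" nucleated cells), class-conditional marker
fluorescence matching the sequential-gating logic of the
leukemia-associated immunophenotype (leukemic = CD19+ CD10+ CD34+/- CD45+/-,
normal = CD19+ CD10- CD34- CD45+, other = CD19- DAPI+ with high side
scatter), per-patient leukemic fractions spanning 0-90%, clump and
out-of-focus contaminants, and the four stained/unstained x laser-on/off
acquisition arms.

The optics are deliberately minimal (disc-shaped cells with a radial
bright-field profile, band-limited intracellular texture, Poisson
dark-field speckle): just enough morphology that class identity is
recoverable from bright-field/dark-field alone, with tunable separation.
All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    CLASS_LABELS,
    DEFAULT_CHANNEL_ROLES,
    FLUOR_ROLES,
    AcquisitionMode,
    CellImage,
    CellRecord,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Background model (documented constants; the 3-px border frame of every
# generated image is pure background, which downstream padding relies on).

BF_BACKGROUND_MEAN = 100.0
BF_BACKGROUND_SD = 4.0
DF_BACKGROUND_MEAN = 20.0
DF_BACKGROUND_SD = 3.0
FLUOR_DETECTOR_MEAN = 10.0
FLUOR_DETECTOR_SD = 2.0

_EDGE_SOFTNESS = 0.7          # px, sigmoid width of the cell boundary
_RIM_GAIN = 20.0              # bright-field rim brightness per unit contrast
_BODY_GAIN = 30.0             # bright-field interior darkening per unit contrast
_NUCLEUS_GAIN = 12.0          # extra darkening of the nucleus
_TEXTURE_GAIN = 9.0           # sd of intracellular texture per unit contrast
_BF2_GAIN = 0.92              # relative gain of the second bright-field camera
_DF_DIFFUSE = 3.0             # diffuse dark-field signal per unit contrast
_SPECKLE_AMP_MEAN = 60.0      # log-normal speckle peak amplitude
_SPECKLE_AMP_SIGMA = 0.4
_OOF_BLUR_SIGMA = 2.5         # px, out-of-focus contaminant blur


@dataclass(frozen=True)
class PhenotypeSpec:
    """Class-conditional generative parameters for one cell class.

    cell_radius_px : (mean, sd) of the disc radius in pixels.
    nucleus_to_cell_ratio : nucleus radius as a fraction of cell radius.
    texture_grain_px : spatial correlation length of intracellular texture.
    darkfield_granularity : expected dark-field speckles per 100 px^2 of
        cell area (side-scatter surrogate; granulocytes are speckle-rich).
    marker_means : role -> (mean amplitude, log-normal sigma) for
        CD10/CD34/CD19/CD45/DAPI/FITC.
    brightfield_contrast : multiplies all bright-field structure.
    """

    class_label: str
    cell_radius_px: tuple[float, float]
    nucleus_to_cell_ratio: float
    texture_grain_px: float
    darkfield_granularity: float
    marker_means: Mapping[str, tuple[float, float]]
    brightfield_contrast: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        mean, sd = self.cell_radius_px
        if mean < 3:
            raise ValidationError("cell_radius_px mean must be >= 3")
        if sd < 0:
            raise ValidationError("cell_radius_px sd must be >= 0")
        if not (0 < self.nucleus_to_cell_ratio <= 1):
            raise ValidationError("nucleus_to_cell_ratio must be in (0, 1]")
        if self.texture_grain_px <= 0:
            raise ValidationError("texture_grain_px must be > 0")
        if self.darkfield_granularity < 0:
            raise ValidationError("darkfield_granularity must be >= 0")
        if self.brightfield_contrast <= 0:
            raise ValidationError("brightfield_contrast must be > 0")
        for role in FLUOR_ROLES:
            if role not in self.marker_means:
                raise ValidationError(f"marker_means missing role {role!r}")
            m, s = self.marker_means[role]
            if m <= 0 or s < 0:
                raise ValidationError(f"marker_means[{role!r}] must be (>0, >=0)")

    def jittered(self, radius_shift: float) -> "PhenotypeSpec":
        """Copy with the radius mean shifted (per-patient heterogeneity)."""
        mean, sd = self.cell_radius_px
        return PhenotypeSpec(
            class_label=self.class_label,
            cell_radius_px=(max(3.0, mean + radius_shift), sd),
            nucleus_to_cell_ratio=self.nucleus_to_cell_ratio,
            texture_grain_px=self.texture_grain_px,
            darkfield_granularity=self.darkfield_granularity,
            marker_means=dict(self.marker_means),
            brightfield_contrast=self.brightfield_contrast,
        )


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Default class phenotypes.

    Morphology: normal B lymphocytes are small and smooth, leukemic blasts
    are larger with finer chromatin texture and moderate granularity,
    "other" (granulocytes/monocytes) are largest and speckle-rich.  Radius
    means are separated by >= 3 sd so the label-free channels carry class
    identity.  Marker amplitudes give >= 10x positive/negative separation
    so sequential gating is a faithful truth oracle; p65-FITC is identical
    across classes (not part of the leukemia-associated immunophenotype).
    """
    common = {"DAPI": (250.0, 0.2), "FITC": (40.0, 0.3)}
    return {
        "leukemic": PhenotypeSpec(
            class_label="leukemic",
            cell_radius_px=(10.0, 0.7),
            nucleus_to_cell_ratio=0.75,
            texture_grain_px=1.0,
            darkfield_granularity=3.0,
            marker_means={
                "CD19": (200.0, 0.25),
                "CD10": (200.0, 0.25),
                "CD34": (90.0, 0.5),   # CD34+/- : broad
                "CD45": (60.0, 0.5),   # CD45+/- : broad
                **common,
            },
            brightfield_contrast=1.0,
        ),
        "normal": PhenotypeSpec(
            class_label="normal",
            cell_radius_px=(6.5, 0.7),
            nucleus_to_cell_ratio=0.8,
            texture_grain_px=2.2,
            darkfield_granularity=0.8,
            marker_means={
                "CD19": (200.0, 0.25),
                "CD10": (15.0, 0.3),
                "CD34": (15.0, 0.3),
                "CD45": (200.0, 0.2),
                **common,
            },
            brightfield_contrast=0.9,
        ),
        "other": PhenotypeSpec(
            class_label="other",
            cell_radius_px=(14.0, 1.0),
            nucleus_to_cell_ratio=0.55,
            texture_grain_px=1.6,
            darkfield_granularity=12.0,
            marker_means={
                "CD19": (15.0, 0.3),
                "CD10": (15.0, 0.3),
                "CD34": (30.0, 0.4),
                "CD45": (150.0, 0.3),
                **common,
            },
            brightfield_contrast=1.1,
        ),
    }


# ---------------------------------------------------------------------------
# Cohort-level specs


@dataclass(frozen=True)
class SampleSpec:
    timepoint_label: str
    n_cells: int
    class_mix: tuple[float, float, float]  # (leukemic, normal, other)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError("n_cells must be >= 1")
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.min() < 0 or mix.max() > 1 or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError("class_mix must be in [0,1] and sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """Patient cohort layout: who is measured when, with what cell mix."""

    patients: tuple[tuple[str, tuple[SampleSpec, ...]], ...]
    contamination: Mapping[str, float] = field(
        default_factory=lambda: {"clump": 0.025, "out_of_focus": 0.025}
    )
    holdout_patient_ids: frozenset[str] = frozenset()
    mode: AcquisitionMode = field(default_factory=AcquisitionMode)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient_id in cohort spec")
        if not set(self.holdout_patient_ids) <= set(ids):
            raise ValidationError("holdout_patient_ids must be a subset of patient ids")
        for kind, frac in self.contamination.items():
            if kind not in ("clump", "out_of_focus"):
                raise ValidationError(f"unknown contamination kind {kind!r}")
            if not (0 <= frac <= 0.5):
                raise ValidationError("contamination fractions must be in [0, 0.5]")


@dataclass
class SampleInfo:
    patient_id: str
    timepoint_label: str
    n_clean: int
    n_contaminant: int
    truth_leukemic_fraction: float  # percent, over clean cells


@dataclass
class Cohort:
    records: list[CellRecord]
    samples: list[SampleInfo]
    holdout_patient_ids: frozenset[str]

    @property
    def train_pool(self) -> list[CellRecord]:
        return [r for r in self.records if r.patient_id not in self.holdout_patient_ids]

    @property
    def holdout_pool(self) -> list[CellRecord]:
        return [r for r in self.records if r.patient_id in self.holdout_patient_ids]


# ---------------------------------------------------------------------------
# Rendering


def _soft_disc(dist: np.ndarray, radius: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip((dist - radius) / _EDGE_SOFTNESS, -40, 40)))


def _cell_fields(
    spec: PhenotypeSpec,
    shape: tuple[int, int],
    center: tuple[float, float],
    rng: np.random.Generator,
) -> dict:
    """Render one cell's noise-free signal contributions on a canvas.

    Returns the soft cell/nucleus masks and the additive bright-field and
    dark-field deltas (background not included).  Consumes only the
    morphology random stream.
    """
    h, w = shape
    radius = max(3.0, rng.normal(*spec.cell_radius_px))
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(yy - center[0], xx - center[1])
    m = _soft_disc(dist, radius)
    mn = _soft_disc(dist, radius * spec.nucleus_to_cell_ratio)

    c = spec.brightfield_contrast
    rim = _RIM_GAIN * c * np.exp(-((dist - radius) ** 2) / (2 * 1.2**2))
    body = -_BODY_GAIN * c * m * (1.0 - 0.5 * (dist / max(radius, 1e-9)) ** 2)
    nucleus = -_NUCLEUS_GAIN * c * mn
    tex = gaussian_filter(rng.standard_normal((h, w)), spec.texture_grain_px)
    tex_sd = tex.std()
    if tex_sd > 1e-12:
        tex = tex / tex_sd
    bf_delta = body + nucleus + rim + _TEXTURE_GAIN * c * tex * m

    # dark-field: diffuse component + Poisson speckle field inside the cell
    df_delta = _DF_DIFFUSE * c * m
    area = math.pi * radius**2
    n_speckles = rng.poisson(spec.darkfield_granularity * area / 100.0)
    for _ in range(n_speckles):
        rho = radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0, 2 * math.pi)
        sy = center[0] + rho * math.sin(theta)
        sx = center[1] + rho * math.cos(theta)
        amp = rng.lognormal(math.log(_SPECKLE_AMP_MEAN), _SPECKLE_AMP_SIGMA)
        sig = rng.uniform(0.7, 1.2)
        r4 = int(math.ceil(4 * sig))
        y0, y1 = max(0, int(sy) - r4), min(h, int(sy) + r4 + 1)
        x0, x1 = max(0, int(sx) - r4), min(w, int(sx) + r4 + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        wy = yy[y0:y1, x0:x1] - sy
        wx = xx[y0:y1, x0:x1] - sx
        df_delta[y0:y1, x0:x1] += amp * np.exp(-(wy**2 + wx**2) / (2 * sig**2))

    return {
        "radius": radius,
        "mask": m,
        "nucleus_mask": mn,
        "bf_delta": bf_delta,
        "df_delta": df_delta,
        "n_speckles": int(n_speckles),
    }


def _assemble(
    fields: Sequence[dict],
    spec_for_markers: Sequence[PhenotypeSpec],
    mode: AcquisitionMode,
    shape: tuple[int, int],
    rng_morph: np.random.Generator,
    rng_fluor: np.random.Generator,
) -> CellImage:
    """Combine rendered cell fields with background and fluorescence."""
    h, w = shape
    n_ch = len(DEFAULT_CHANNEL_ROLES)
    pixels = np.zeros((n_ch, h, w), dtype=np.float32)
    roles = DEFAULT_CHANNEL_ROLES

    bf_delta = sum(f["bf_delta"] for f in fields)
    df_delta = sum(f["df_delta"] for f in fields)

    bf1 = BF_BACKGROUND_MEAN + rng_morph.normal(0, BF_BACKGROUND_SD, (h, w)) + bf_delta
    bf2 = (
        BF_BACKGROUND_MEAN
        + rng_morph.normal(0, BF_BACKGROUND_SD, (h, w))
        + _BF2_GAIN * bf_delta
    )
    df = DF_BACKGROUND_MEAN + rng_morph.normal(0, DF_BACKGROUND_SD, (h, w)) + df_delta

    fluor: dict[str, np.ndarray] = {}
    total_amp = 0.0
    for role in FLUOR_ROLES:
        plane = FLUOR_DETECTOR_MEAN + rng_fluor.normal(0, FLUOR_DETECTOR_SD, (h, w))
        if mode.fluorescence_active:
            for f, spec in zip(fields, spec_for_markers):
                mean, sigma = spec.marker_means[role]
                amp = rng_fluor.lognormal(math.log(mean), sigma)
                total_amp += amp
                carrier = f["nucleus_mask"] if role == "DAPI" else f["mask"]
                plane = plane + amp * carrier
        fluor[role] = plane

    if mode.fluorescence_active and mode.bleedthrough_coeff > 0:
        union = np.maximum.reduce([f["mask"] for f in fields])
        bleed = mode.bleedthrough_coeff * total_amp * union
        bf1 = bf1 + bleed
        bf2 = bf2 + bleed

    for idx, role in enumerate(roles):
        if role == "BF1":
            pixels[idx] = bf1
        elif role == "BF2":
            pixels[idx] = bf2
        elif role == "DF":
            pixels[idx] = df
        elif role in fluor:
            pixels[idx] = fluor[role]
        # unused channels stay zero-filled

    np.clip(pixels, 0, None, out=pixels)
    return CellImage(pixels=pixels.astype(np.float32), channel_roles=roles)


def generate_cell(
    spec: PhenotypeSpec,
    mode: AcquisitionMode,
    rng: np.random.Generator,
    side: Optional[int] = None,
) -> CellImage:
    """Generate one clean cell image (12 channels, side 40-64 px).

    Bright-field/dark-field content depends only on the morphology stream,
    so for a fixed seed it is identical across the four acquisition modes
    (up to bleed-through); fluorescence channels carry marker signal only
    when stained and laser-on, otherwise detector noise alone.
    """
    rng_morph, rng_fluor = rng.spawn(2)
    r_mean, r_sd = spec.cell_radius_px
    if side is None:
        lo = int(min(64, max(40, math.ceil(2 * (r_mean + 3 * r_sd + 6)))))
        side = int(rng_morph.integers(lo, 65))
    elif side < 8:
        raise ValidationError("side must be >= 8")
    center = (
        side / 2 + rng_morph.uniform(-2, 2),
        side / 2 + rng_morph.uniform(-2, 2),
    )
    f = _cell_fields(spec, (side, side), center, rng_morph)
    return _assemble([f], [spec], mode, (side, side), rng_morph, rng_fluor)


def _generate_clump(
    spec: PhenotypeSpec,
    mode: AcquisitionMode,
    rng: np.random.Generator,
) -> CellImage:
    """Two overlapping cells of the same class (doublet contaminant)."""
    rng_morph, rng_fluor = rng.spawn(2)
    side = 64
    r_mean, _ = spec.cell_radius_px
    u = rng_morph.uniform(0.6, 0.9)
    d = min(u * 2 * r_mean, side - 2 * (r_mean + 6))
    theta = rng_morph.uniform(0, 2 * math.pi)
    mid = side / 2
    c1 = (mid - d / 2 * math.sin(theta), mid - d / 2 * math.cos(theta))
    c2 = (mid + d / 2 * math.sin(theta), mid + d / 2 * math.cos(theta))
    f1 = _cell_fields(spec, (side, side), c1, rng_morph)
    f2 = _cell_fields(spec, (side, side), c2, rng_morph)
    return _assemble([f1, f2], [spec, spec], mode, (side, side), rng_morph, rng_fluor)


def _defocus(image: CellImage, sigma: float = _OOF_BLUR_SIGMA) -> CellImage:
    blurred = gaussian_filter(image.pixels, (0, sigma, sigma))
    return CellImage(
        pixels=blurred.astype(np.float32),
        channel_roles=image.channel_roles,
        pixel_size_um=image.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Samples and cohorts


def generate_sample(
    patient_id: str,
    timepoint_label: str,
    n_cells: int,
    class_mix: Sequence[float],
    contamination: Mapping[str, float],
    mode: AcquisitionMode,
    rng: np.random.Generator,
    phenotypes: Optional[Mapping[str, PhenotypeSpec]] = None,
) -> list[CellRecord]:
    """Generate one sample: n_cells clean cells plus flagged contaminants.

    Clean true classes are i.i.d. draws from class_mix; contaminant counts
    are floor(fraction * n_cells) per kind.  Record order is shuffled.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if abs(mix.sum() - 1.0) > 1e-9 or mix.min() < 0:
        raise ValidationError("class_mix must be nonnegative and sum to 1")
    specs = dict(phenotypes) if phenotypes is not None else default_phenotypes()

    classes = list(rng.choice(CLASS_LABELS, size=n_cells, p=mix))
    jobs: list[tuple[str, Optional[str]]] = [(c, None) for c in classes]
    for kind, frac in contamination.items():
        n_extra = int(frac * n_cells)
        extra_classes = rng.choice(CLASS_LABELS, size=n_extra, p=mix)
        jobs.extend((c, kind) for c in extra_classes)

    order = rng.permutation(len(jobs))
    records = []
    for serial, j in enumerate(order):
        cls, kind = jobs[j]
        cell_rng = rng.spawn(1)[0]
        if kind == "clump":
            image = _generate_clump(specs[cls], mode, cell_rng)
        else:
            image = generate_cell(specs[cls], mode, cell_rng)
            if kind == "out_of_focus":
                image = _defocus(image)
        records.append(
            CellRecord(
                image=image,
                cell_id=f"{patient_id}|{timepoint_label}|{serial:05d}",
                patient_id=patient_id,
                timepoint_label=timepoint_label,
                acquisition=mode,
                true_class=cls,
                contaminant=kind,
            )
        )
    return records


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full multi-patient cohort from a CohortSpec.

    Each patient's phenotypes get a small deterministic radius jitter
    (patient heterogeneity).  Per-sample true leukemic fractions are
    recorded over clean cells only, for later residual-disease truth.
    """
    base = default_phenotypes()
    root = np.random.default_rng(np.random.SeedSequence(spec.seed))
    records: list[CellRecord] = []
    samples: list[SampleInfo] = []
    for patient_id, sample_specs in spec.patients:
        prng = root.spawn(1)[0]
        jitter = {c: prng.normal(0, 0.15) for c in CLASS_LABELS}
        phenos = {c: base[c].jittered(jitter[c]) for c in CLASS_LABELS}
        for ss in sample_specs:
            srng = prng.spawn(1)[0]
            recs = generate_sample(
                patient_id,
                ss.timepoint_label,
                ss.n_cells,
                ss.class_mix,
                spec.contamination,
                spec.mode,
                srng,
                phenotypes=phenos,
            )
            clean = [r for r in recs if r.contaminant is None]
            n_leuk = sum(r.true_class == "leukemic" for r in clean)
            samples.append(
                SampleInfo(
                    patient_id=patient_id,
                    timepoint_label=ss.timepoint_label,
                    n_clean=len(clean),
                    n_contaminant=len(recs) - len(clean),
                    truth_leukemic_fraction=100.0 * n_leuk / len(clean),
                )
            )
            records.extend(recs)
    return Cohort(
        records=records,
        samples=samples,
        holdout_patient_ids=frozenset(spec.holdout_patient_ids),
    )
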