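"""Core containers for per-cell imaging-flow-cytometry data.

The instrument records each cell as a 12-channel image stack: two
bright-field channels (transmitted light, cameras 1 and 2), one dark-field
channel (a side-scatter surrogate), and fluorescence channels for the
B-lineage marker panel (CD10, CD34, DAPI, CD19, CD45) plus one
non-discriminative FITC channel.  Channels not listed carry no signal and
are kept zero-filled so that channel-subset logic is exercised on realistic
12-plane stacks.

Coordinates are row-major, origin top-left, 0-based, half-open slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

CLASS_LABELS = ("leukemic", "normal", "other")

#: Channel roles in instrument order (index 0 == instrument channel 1).
#: Bright-field in channels 1 and 9, dark-field in channel 6, CD10 in 3,
#: CD34 in 4, DAPI in 7, CD19 in 11, CD45 in 12.  The FITC channel is not
#: documented by the instrument layout; it is placed in channel 2.
DEFAULT_CHANNEL_ROLES = (
    "BF1",      # ch1  camera 1 bright-field
    "FITC",     # ch2  p65-FITC, non-discriminative
    "CD10",     # ch3
    "CD34",     # ch4
    "unused5",  # ch5
    "DF",       # ch6  dark-field (side-scatter surrogate)
    "DAPI",     # ch7  nuclear stain
    "unused8",  # ch8
    "BF2",      # ch9  camera 2 bright-field
    "unused10", # ch10
    "CD19",     # ch11
    "CD45",     # ch12
)

LABEL_FREE_ROLES = ("BF1", "BF2", "DF")
FLUOR_ROLES = ("CD10", "CD34", "DAPI", "CD19", "CD45", "FITC")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass(frozen=True)
class AcquisitionMode:
    """How a sample was acquired.

    ``stained`` and ``laser_on`` select one of the four acquisition arms of
    the stained/unstained x laser-on/off control experiment.  Fluorescence
    channels carry marker signal only when both are true; otherwise they
    contain detector noise.  ``bleedthrough_coeff`` is the fraction of the
    summed fluorescence amplitude leaking into the bright-field channels
    when stained and laser-on (0 = no spillover).
    """

    stained: bool = True
    laser_on: bool = True
    bleedthrough_coeff: float = 0.0

    def __post_init__(self) -> None:
        if self.bleedthrough_coeff < 0:
            raise ValidationError("bleedthrough_coeff must be >= 0")

    @property
    def fluorescence_active(self) -> bool:
        return self.stained and self.laser_on


@dataclass
class CellImage:
    """One cell's multi-channel pixel stack.

    pixels : (channels, height, width) nonnegative float32 array
    channel_roles : role name per plane; the single source of truth for
        channel identity — readers and writers never reorder planes.
    pixel_size_um : physical pixel pitch (0.3 um at 40x magnification).
    """

    pixels: np.ndarray
    channel_roles: tuple[str, ...] = DEFAULT_CHANNEL_ROLES
    pixel_size_um: float = 0.3

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_roles = tuple(self.channel_roles)
        if self.pixels.ndim != 3:
            raise ValidationError("pixels must be (channels, height, width)")
        c, h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValidationError("image height and width must be >= 8")
        if len(self.channel_roles) != c:
            raise ValidationError(
                f"channel_roles has {len(self.channel_roles)} entries "
                f"for {c} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def side(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, role: str) -> np.ndarray:
        """Return the pixel plane for a role (error if absent)."""
        try:
            idx = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(f"role {role!r} not in channel_roles") from None
        return self.pixels[idx]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles


@dataclass
class CellRecord:
    """A CellImage plus provenance and (optional) ground truth."""

    image: CellImage
    cell_id: str
    patient_id: str
    timepoint_label: str
    acquisition: AcquisitionMode = field(default_factory=AcquisitionMode)
    true_class: Optional[str] = None
    contaminant: Optional[str] = None  # 'clump' | 'out_of_focus' | None
    qc: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.timepoint_label:
            raise ValidationError("timepoint_label must be non-empty")
        if self.true_class is not None and self.true_class not in CLASS_LABELS:
            raise ValidationError(
                f"true_class must be one of {CLASS_LABELS}, got {self.true_class!r}"
            )
        if self.contaminant not in (None, "clump", "out_of_focus"):
            raise ValidationError(f"unknown contaminant tag {self.contaminant!r}")

    @property
    def sample_id(self) -> tuple[str, str]:
        return (self.patient_id, self.timepoint_label)

    def with_image(self, image: CellImage) -> "CellRecord":
        return replace(self, image=image)


def check_unique_cell_ids(records: Sequence[CellRecord]) -> None:
    ids = [r.cell_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("cell_id values must be unique within a cohort")
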