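"""Open on-disk container for per-cell images, and montage stitching.

The vendor's .CIF container is proprietary, so the native format here is
open: one multi-page TIFF per cell (one page per channel, in channel-role
order) plus a single TSV metadata table.  A conversion seam is provided by
``read_cells``'s record-level API — any adapter that yields CellRecords
can feed the pipeline.

Montages mirror the cytometer-export step in which single-cell crops are
tiled into a grid image for downstream segmentation: tiles are placed
row-major, origin top-left, and stitching/splitting is lossless.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import AcquisitionMode, CellImage, CellRecord, ValidationError

MANIFEST_NAME = "cells.tsv"

_SCALAR_COLUMNS = [
    "cell_id",
    "patient_id",
    "timepoint_label",
    "true_class",
    "contaminant",
    "stained",
    "laser_on",
    "bleedthrough_coeff",
    "pixel_size_um",
    "channel_roles",
    "file",
]


def _safe_name(cell_id: str) -> str:
    return "".join(ch if (ch.isalnum() or ch in "-_.") else "_" for ch in cell_id)


def write_cells(records: Sequence[CellRecord], directory: str | os.PathLike) -> Path:
    """Write records as per-cell multi-page TIFFs plus a TSV manifest.

    Returns the manifest path.  The round trip through ``read_cells`` is
    bit-exact for both pixel data (dtype preserved) and metadata.
    """
    if not records:
        raise ValidationError("records must be non-empty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"{i:06d}_{_safe_name(rec.cell_id)}.tif"
        tifffile.imwrite(directory / fname, rec.image.pixels, photometric="minisblack")
        rows.append(
            {
                "cell_id": rec.cell_id,
                "patient_id": rec.patient_id,
                "timepoint_label": rec.timepoint_label,
                "true_class": rec.true_class if rec.true_class is not None else "",
                "contaminant": rec.contaminant if rec.contaminant is not None else "",
                "stained": int(rec.acquisition.stained),
                "laser_on": int(rec.acquisition.laser_on),
                "bleedthrough_coeff": repr(rec.acquisition.bleedthrough_coeff),
                "pixel_size_um": repr(rec.image.pixel_size_um),
                "channel_roles": ",".join(rec.image.channel_roles),
                "file": fname,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=_SCALAR_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cells(directory: str | os.PathLike) -> list[CellRecord]:
    """Read a directory written by ``write_cells`` back into records."""
    directory = Path(directory)
    manifest = directory / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} manifest in {directory}")
    table = pd.read_csv(manifest, sep="\t", keep_default_na=False, dtype=str)
    records = []
    for row in table.itertuples(index=False):
        path = directory / row.file
        if not path.exists():
            raise FileNotFoundError(
                f"cell {row.cell_id!r}: image file {row.file} missing"
            )
        pixels = tifffile.imread(path)
        if pixels.ndim == 2:
            pixels = pixels[None]
        roles = tuple(row.channel_roles.split(","))
        if len(roles) != pixels.shape[0]:
            raise ValidationError(
                f"cell {row.cell_id!r}: manifest lists {len(roles)} channels "
                f"but TIFF has {pixels.shape[0]} pages"
            )
        records.append(
            CellRecord(
                image=CellImage(
                    pixels=pixels,
                    channel_roles=roles,
                    pixel_size_um=float(row.pixel_size_um),
                ),
                cell_id=row.cell_id,
                patient_id=row.patient_id,
                timepoint_label=row.timepoint_label,
                acquisition=AcquisitionMode(
                    stained=bool(int(row.stained)),
                    laser_on=bool(int(row.laser_on)),
                    bleedthrough_coeff=float(row.bleedthrough_coeff),
                ),
                true_class=row.true_class or None,
                contaminant=row.contaminant or None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Montage


@dataclass(frozen=True)
class MontageIndex:
    """Grid layout of a montage: which cell occupies which slot (row-major)."""

    rows: int
    cols: int
    tile_side: int
    cell_ids: tuple[str, ...]
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.rows * self.cols < len(self.cell_ids):
            raise ValidationError("grid too small for the number of cells")

    def slot(self, k: int) -> tuple[slice, slice]:
        r, c = divmod(k, self.cols)
        t = self.tile_side
        return slice(r * t, (r + 1) * t), slice(c * t, (c + 1) * t)


def stitch_montage(
    records: Sequence[CellRecord],
    tile_side: int,
    grid: tuple[int, int],
) -> tuple[np.ndarray, MontageIndex]:
    """Tile per-cell images into a (channels, rows*t, cols*t) montage.

    Images smaller than ``tile_side`` are placed at the top-left of their
    slot; larger images are an error (standardize the canvas first).
    Empty trailing slots hold the fill value.
    """
    if not records:
        raise ValidationError("records must be non-empty")
    rows, cols = grid
    index = MontageIndex(
        rows=rows,
        cols=cols,
        tile_side=tile_side,
        cell_ids=tuple(r.cell_id for r in records),
    )
    n_ch = records[0].image.n_channels
    montage = np.full(
        (n_ch, rows * tile_side, cols * tile_side),
        index.fill_value,
        dtype=records[0].image.pixels.dtype,
    )
    for k, rec in enumerate(records):
        h, w = rec.image.side
        if h > tile_side or w > tile_side:
            raise ValidationError(
                f"cell {rec.cell_id!r} is {h}x{w}, larger than tile_side={tile_side}"
            )
        if rec.image.n_channels != n_ch:
            raise ValidationError("all records must share a channel count")
        rs, cs = index.slot(k)
        montage[:, rs, cs][:, :h, :w] = rec.image.pixels
    return montage, index


def split_montage(montage: np.ndarray, index: MontageIndex) -> list[np.ndarray]:
    """Recover the per-cell pixel tiles (tile_side square) from a montage."""
    t = index.tile_side
    if montage.shape[1] < index.rows * t or montage.shape[2] < index.cols * t:
        raise ValidationError("montage smaller than the index grid")
    tiles = []
    for k in range(len(index.cell_ids)):
        rs, cs = index.slot(k)
        tiles.append(montage[:, rs, cs].copy())
    return tiles


def write_montage(
    montage: np.ndarray, index: MontageIndex, path: str | os.PathLike
) -> Path:
    """Write a montage as multi-page TIFF with a sidecar TSV index."""
    path = Path(path)
    tifffile.imwrite(path, montage, photometric="minisblack")
    side = path.with_suffix(".index.tsv")
    meta = pd.DataFrame(
        {"slot": range(len(index.cell_ids)), "cell_id": index.cell_ids}
    )
    with open(side, "w") as fh:
        fh.write(
            f"# rows={index.rows}\tcols={index.cols}"
            f"\ttile_side={index.tile_side}\tfill_value={index.fill_value!r}\n"
        )
        meta.to_csv(fh, sep="\t", index=False)
    return path


def read_montage(path: str | os.PathLike) -> tuple[np.ndarray, MontageIndex]:
    path = Path(path)
    montage = tifffile.imread(path)
    if montage.ndim == 2:
        montage = montage[None]
    side = path.with_suffix(".index.tsv")
    with open(side) as fh:
        header = fh.readline().lstrip("#").strip()
        kv = dict(item.split("=", 1) for item in header.split("\t"))
        meta = pd.read_csv(fh, sep="\t", dtype={"cell_id": str})
    index = MontageIndex(
        rows=int(kv["rows"]),
        cols=int(kv["cols"]),
        tile_side=int(kv["tile_side"]),
        cell_ids=tuple(meta["cell_id"]),
        fill_value=float(kv["fill_value"]),
    )
    return montage, index
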