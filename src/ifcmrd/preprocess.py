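"""Canvas standardization, contrast stretching, centering, augmentation.

The training-time transform chain is canvas -> stretch -> center ->
augment; at inference the chain is canvas -> stretch -> center with the
training-set channel means and no augmentation.

Canvas standardization resizes every cell image to 48x48 by center-cropping
peripheral background or by padding channel-wise with noise sampled from
the image's own background (the empirical distribution of its outermost
3-px border frame).  Contrast stretching rescales each channel between its
0.5 and 99.5 percentiles to the full uint8 range [0, 256).  Percentiles
use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import affine_transform

from .core import CellImage, CellRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SIDE = 48
BORDER_FRAME_PX = 3

_WARNED_CONSTANT_CHANNELS: set[str] = set()


@dataclass(frozen=True)
class AugmentPolicy:
    """Random flips, shifts up to half the image side, rotations to 180 deg."""

    flip_horizontal: bool = True
    flip_vertical: bool = True
    max_shift_fraction: float = 0.5
    max_rotation_deg: float = 180.0

    def __post_init__(self) -> None:
        if not (0 <= self.max_shift_fraction <= 0.5):
            raise ValidationError("max_shift_fraction must be in [0, 0.5]")
        if not (0 <= self.max_rotation_deg <= 180):
            raise ValidationError("max_rotation_deg must be in [0, 180]")

    @classmethod
    def disabled(cls) -> "AugmentPolicy":
        return cls(False, False, 0.0, 0.0)


@dataclass(frozen=True)
class ChannelMeans:
    """Per-channel scalar means, computed on the training partition only."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in self.values):
            raise ValidationError("channel means must be finite")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float32)


def border_frame(plane: np.ndarray, width: int = BORDER_FRAME_PX) -> np.ndarray:
    """Flattened pixels of the outermost ``width``-px frame of a 2-D plane."""
    h, w = plane.shape
    width = min(width, h // 2, w // 2)
    if width == 0:
        return plane.ravel()
    mask = np.zeros((h, w), dtype=bool)
    mask[:width, :] = mask[-width:, :] = True
    mask[:, :width] = mask[:, -width:] = True
    return plane[mask]


def _crop_axis(n: int, side: int) -> slice:
    start = (n - side) // 2
    return slice(start, start + side)


def standardize_canvas(
    image: CellImage,
    side: int = DEFAULT_SIDE,
    rng: Optional[np.random.Generator] = None,
) -> CellImage:
    """Center-crop or background-noise-pad each channel to side x side.

    Padding values are drawn per-channel from that channel's 3-px border
    frame, so the padded margin is statistically indistinguishable from
    the image's own background.  Idempotent on already side x side inputs.
    """
    if side < 8:
        raise ValidationError("side must be >= 8")
    c, h, w = image.pixels.shape
    if (h, w) == (side, side):
        return image
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty((c, side, side), dtype=image.pixels.dtype)
    # per-axis: crop if larger, pad symmetrically if smaller
    src_r = _crop_axis(h, min(h, side))
    src_c = _crop_axis(w, min(w, side))
    pad_r = (side - min(h, side)) // 2
    pad_c = (side - min(w, side)) // 2
    dst_r = slice(pad_r, pad_r + min(h, side))
    dst_c = slice(pad_c, pad_c + min(w, side))
    for k in range(c):
        plane = image.pixels[k]
        frame = border_frame(plane)
        out[k] = rng.choice(frame, size=(side, side))
        out[k][dst_r, dst_c] = plane[src_r, src_c]
    return CellImage(
        pixels=out, channel_roles=image.channel_roles, pixel_size_um=image.pixel_size_um
    )


def contrast_stretch(
    image: CellImage, p_low: float = 0.5, p_high: float = 99.5
) -> CellImage:
    """Rescale each channel's [p_low, p_high] percentile band to uint8.

    v' = floor(256 * clip((v - q_low)/(q_high - q_low), 0, 1)), capped at
    255: values at/below q_low map to 0, at/above q_high map to 255.
    A constant channel maps to all zeros (warning logged).
    """
    if not (0 <= p_low < p_high <= 100):
        raise ValidationError("need 0 <= p_low < p_high <= 100")
    c = image.pixels.shape[0]
    out = np.empty_like(image.pixels, dtype=np.uint8)
    for k in range(c):
        plane = np.asarray(image.pixels[k], dtype=np.float64)
        q_low, q_high = np.percentile(plane, [p_low, p_high])
        if q_high <= q_low:
            role = image.channel_roles[k]
            if role not in _WARNED_CONSTANT_CHANNELS:
                _WARNED_CONSTANT_CHANNELS.add(role)
                logger.warning(
                    "constant channel %r: contrast stretch maps it to zeros "
                    "(warned once per role)", role,
                )
            out[k] = 0
            continue
        scaled = np.clip((plane - q_low) / (q_high - q_low), 0.0, 1.0)
        out[k] = np.minimum(np.floor(scaled * 256.0), 255.0).astype(np.uint8)
    return CellImage(
        pixels=out, channel_roles=image.channel_roles, pixel_size_um=image.pixel_size_um
    )


def compute_channel_means(images: Iterable[np.ndarray]) -> ChannelMeans:
    """Channel-wise means over a stack of (C, H, W) arrays (training set)."""
    total = None
    count = 0
    for arr in images:
        arr = np.asarray(arr, dtype=np.float64)
        s = arr.sum(axis=(1, 2))
        total = s if total is None else total + s
        count += arr.shape[1] * arr.shape[2]
    if total is None:
        raise ValidationError("need at least one image")
    return ChannelMeans(values=tuple(total / count))


def zero_center(pixels: np.ndarray, means: ChannelMeans) -> np.ndarray:
    """Subtract per-channel training means; accepts (C,H,W) or (N,C,H,W)."""
    arr = np.asarray(pixels, dtype=np.float32)
    mu = means.as_array()
    if arr.ndim == 3:
        if arr.shape[0] != mu.size:
            raise ValidationError("channel count does not match means")
        return arr - mu[:, None, None]
    if arr.ndim == 4:
        if arr.shape[1] != mu.size:
            raise ValidationError("channel count does not match means")
        return arr - mu[None, :, None, None]
    raise ValidationError("pixels must be (C,H,W) or (N,C,H,W)")


# ---------------------------------------------------------------------------
# Augmentation


def apply_augment(
    pixels: np.ndarray,
    flip_h: bool,
    flip_v: bool,
    shift: tuple[int, int],
    angle_deg: float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Deterministic augmentation primitive on a (C, H, W) array.

    Flips are exact; integer shift and rotation go through one bilinear
    affine transform whose out-of-support pixels are filled with noise
    drawn from the channel's border frame (consistent with canvas
    padding).  With no shift and no rotation the transform is skipped, so
    flips alone are exactly involutive.
    """
    arr = np.asarray(pixels)
    if flip_h:
        arr = arr[:, :, ::-1]
    if flip_v:
        arr = arr[:, ::-1, :]
    dy, dx = shift
    if dy == 0 and dx == 0 and angle_deg == 0.0:
        return np.ascontiguousarray(arr)
    if rng is None:
        rng = np.random.default_rng(0)
    c, h, w = arr.shape
    theta = np.deg2rad(angle_deg)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rot = np.array([[cos_t, -sin_t], [sin_t, cos_t]])
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    # output coordinate -> input coordinate: rotate about center, then shift
    offset2 = center - rot @ center - rot @ np.array([dy, dx])
    matrix = np.eye(3)
    matrix[1:, 1:] = rot
    arr32 = np.ascontiguousarray(arr, dtype=np.float32)
    warped = affine_transform(
        arr32,
        matrix,
        offset=np.array([0.0, offset2[0], offset2[1]]),
        order=1,
        mode="constant",
        cval=np.nan,
    )
    missing = np.isnan(warped)
    if missing.any():
        for k in range(c):
            mk = missing[k]
            n_miss = int(mk.sum())
            if n_miss:
                frame = border_frame(arr32[k])
                warped[k][mk] = rng.choice(frame, size=n_miss)
    return warped


def _draw_augment_params(
    side: int, policy: AugmentPolicy, rng: np.random.Generator
) -> tuple[bool, bool, tuple[int, int], float]:
    flip_h = policy.flip_horizontal and bool(rng.integers(2))
    flip_v = policy.flip_vertical and bool(rng.integers(2))
    max_shift = int(policy.max_shift_fraction * side)
    if max_shift > 0:
        shift = (
            int(rng.integers(-max_shift, max_shift + 1)),
            int(rng.integers(-max_shift, max_shift + 1)),
        )
    else:
        shift = (0, 0)
    angle = (
        float(rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg))
        if policy.max_rotation_deg > 0
        else 0.0
    )
    return flip_h, flip_v, shift, angle


def augment_batch(
    batch: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-image random flip/shift/rotation over a (N, C, H, W) batch.

    Parameters are drawn per image; the bilinear warp itself is a single
    vectorized gather over the batch.  Out-of-support pixels are filled
    with noise from the image's own channel border frames, as in the
    single-image path.
    """
    arr = np.asarray(batch, dtype=np.float32)
    n, c, h, w = arr.shape
    params = [_draw_augment_params(w, policy, rng) for _ in range(n)]

    flipped = arr.copy()
    fh = np.array([p[0] for p in params])
    fv = np.array([p[1] for p in params])
    if fh.any():
        flipped[fh] = flipped[fh][:, :, :, ::-1]
    if fv.any():
        flipped[fv] = flipped[fv][:, :, ::-1, :]

    dy = np.array([p[2][0] for p in params], dtype=np.float64)
    dx = np.array([p[2][1] for p in params], dtype=np.float64)
    theta = np.deg2rad([p[3] for p in params])
    cos_t = np.cos(theta)[:, None, None]
    sin_t = np.sin(theta)[:, None, None]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # output coordinate -> input coordinate, matching the single-image
    # path: input = rot @ out + (center - rot@center - rot@shift)
    iy = (
        cos_t * (yy[None] - cy) - sin_t * (xx[None] - cx)
        + cy - cos_t * dy[:, None, None] + sin_t * dx[:, None, None]
    )
    ix = (
        sin_t * (yy[None] - cy) + cos_t * (xx[None] - cx)
        + cx - sin_t * dy[:, None, None] - cos_t * dx[:, None, None]
    )

    invalid = (iy < 0) | (iy > h - 1) | (ix < 0) | (ix > w - 1)
    y0 = np.floor(iy).astype(np.int64)
    x0 = np.floor(ix).astype(np.int64)
    fy = (iy - y0).astype(np.float32)[..., None]
    fx = (ix - x0).astype(np.float32)[..., None]
    y0c = np.clip(y0, 0, h - 1)
    y1c = np.clip(y0 + 1, 0, h - 1)
    x0c = np.clip(x0, 0, w - 1)
    x1c = np.clip(x0 + 1, 0, w - 1)

    # channels-last so one fancy index gathers all channels at once
    flc = np.ascontiguousarray(flipped.transpose(0, 2, 3, 1))
    bidx = np.arange(n)[:, None, None]
    outc = (
        (1 - fy) * (1 - fx) * flc[bidx, y0c, x0c]
        + (1 - fy) * fx * flc[bidx, y0c, x1c]
        + fy * (1 - fx) * flc[bidx, y1c, x0c]
        + fy * fx * flc[bidx, y1c, x1c]
    )

    ik, yk, xk = np.nonzero(invalid)
    if len(ik):
        frame_mask = np.zeros((h, w), dtype=bool)
        bw = min(BORDER_FRAME_PX, h // 2, w // 2)
        frame_mask[:bw, :] = frame_mask[-bw:, :] = True
        frame_mask[:, :bw] = frame_mask[:, -bw:] = True
        borders = flipped[:, :, frame_mask]  # (N, C, nb)
        nb = borders.shape[2]
        pick = rng.integers(nb, size=(len(ik), c), dtype=np.int64)
        outc[ik, yk, xk] = borders[ik[:, None], np.arange(c)[None, :], pick]
    return np.ascontiguousarray(outc.transpose(0, 3, 1, 2), dtype=np.float32)


def augment(
    pixels: np.ndarray,
    policy: AugmentPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random flip/shift/rotation per the policy on a (C, H, W) array."""
    flip_h, flip_v, shift, angle = _draw_augment_params(
        pixels.shape[-1], policy, rng
    )
    return apply_augment(pixels, flip_h, flip_v, shift, angle, rng)


# ---------------------------------------------------------------------------
# The transform chains


@dataclass(frozen=True)
class PreprocessChain:
    """Shared canvas/stretch settings plus the training augmentation policy."""

    side: int = DEFAULT_SIDE
    p_low: float = 0.5
    p_high: float = 99.5
    policy: AugmentPolicy = AugmentPolicy()

    def base(self, image: CellImage, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """canvas -> stretch; returns uint8 (C, side, side) pixels."""
        std = standardize_canvas(image, self.side, rng)
        return contrast_stretch(std, self.p_low, self.p_high).pixels

    def base_records(
        self, records: Sequence[CellRecord], rng: Optional[np.random.Generator] = None
    ) -> np.ndarray:
        """canvas -> stretch for a batch of records.

        Without an explicit rng (the inference path) each record gets a
        fresh fixed-seed generator, so padding noise is a pure function of
        the image alone and identical cells map to identical tensors.
        """
        if rng is None:
            return np.stack(
                [self.base(r.image, np.random.default_rng(0)) for r in records]
            )
        return np.stack([self.base(r.image, rng) for r in records])

    def train_batch(
        self, base_pixels: np.ndarray, means: ChannelMeans, rng: np.random.Generator
    ) -> np.ndarray:
        """center -> augment, per image of a (N, C, H, W) uint8 stack.

        Augmentation parameters are drawn per image but the bilinear warp
        runs vectorized over the whole batch.
        """
        centered = zero_center(base_pixels, means)
        return augment_batch(centered, self.policy, rng)

    def eval_batch(self, base_pixels: np.ndarray, means: ChannelMeans) -> np.ndarray:
        """center only — no augmentation at inference."""
        return zero_center(base_pixels, means)
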