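"""Two-step rigid registration of a CK slide onto its re-stained H&E slide.

Re-staining the same physical section leaves essentially no non-rigid
deformation, only a translation.  Alignment therefore reduces to shift
estimation: binarize a stain channel in each image (eosin for H&E, DAB for
CK) with locally adaptive thresholding, and take the argmax of their linear
cross-correlation, computed via FFT.  A coarse global shift is estimated on
32x-downsampled slides; residual local shifts are then estimated per region
from per-patch correlations with outlier rejection.

Sign convention: a shift ``(drow, dcol)`` states that CK content sits that
many level-0 pixels down/right of the matching H&E content; sampling the CK
raster at ``(r + drow, c + dcol)`` lands it on the H&E frame.  Coordinates
are 0-based, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_local
from skimage.measure import block_reduce
from skimage.morphology import remove_small_objects

from .patchflow import is_white_background
from .stains import RGBImage, StainBasis, dab_channel_8bit, eosin_channel_8bit

__all__ = [
    "ShiftVector",
    "LocalShiftMap",
    "registration_mask",
    "shift_from_cross_correlation",
    "estimate_global_shift",
    "estimate_local_shifts",
]


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable foreground signal."""


@dataclass(frozen=True)
class ShiftVector:
    """Integer translation in pixels at a stated pyramid scale."""

    drow: int
    dcol: int
    level_scale: int = 1

    def at_level0(self) -> "ShiftVector":
        return ShiftVector(self.drow * self.level_scale, self.dcol * self.level_scale, 1)

    def __iter__(self):
        yield self.drow
        yield self.dcol


@dataclass
class LocalShiftMap:
    """Final per-region shifts: (region origin at level 0) -> ShiftVector."""

    entries: list[tuple[tuple[int, int], ShiftVector]] = field(default_factory=list)
    region_size: int = 10240
    inlier_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def shift_at(self, origin: tuple[int, int]) -> ShiftVector:
        for o, s in self.entries:
            if o == origin:
                return s
        raise KeyError(origin)


def registration_mask(
    channel: np.ndarray,
    block_size: int = 151,
    offset: float = 10.0,
    min_area: int = 200,
) -> np.ndarray:
    """Binarize a stain-channel raster for cross-correlation.

    A pixel is foreground iff its value exceeds the Gaussian-weighted local
    mean (window ``block_size``, sigma ``(block_size - 1) / 6``, reflect
    boundary) minus ``offset``.  8-connected foreground components with area
    strictly below ``min_area`` are then removed.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be an odd integer >= 3")
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D raster")
    thresh = threshold_local(img, block_size=block_size, method="gaussian", offset=offset)
    mask = img > thresh
    if min_area > 1:
        # removes components with area <= min_area - 1, i.e. strictly below min_area
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    return mask


def shift_from_cross_correlation(mask_ref: np.ndarray, mask_mov: np.ndarray) -> ShiftVector:
    """Shift maximizing the zero-padded linear cross-correlation of two masks.

    Returns the integer displacement ``(drow, dcol)`` of ``mask_mov``'s
    content relative to ``mask_ref``: if ``mask_mov`` equals ``mask_ref``
    translated down/right by ``(p, q)``, the result is ``(p, q)``, and
    sampling ``mask_mov`` at ``(r + p, c + q)`` realigns it.  Ties break
    toward the lexicographically smallest shift.  Correlation is computed
    via FFT and rounded to integer counts (binary inputs) so ties are exact.
    """
    a = np.asarray(mask_ref, dtype=float)
    b = np.asarray(mask_mov, dtype=float)
    if a.shape != b.shape:
        raise ValueError("masks must have identical shape")
    if a.sum() == 0 or b.sum() == 0:
        raise DegenerateInputError("empty registration mask")
    # corr[d] = sum_t ref[t] * mov[t + d]  ==  conv(mov, flip(ref))[d + shape - 1]
    corr = fftconvolve(b, a[::-1, ::-1], mode="full")
    corr = np.rint(corr).astype(np.int64)
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    drow = int(idx[0]) - (a.shape[0] - 1)
    dcol = int(idx[1]) - (a.shape[1] - 1)
    return ShiftVector(drow, dcol)


def _downsample_channel(channel: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool a channel by an integer factor (partial edge blocks kept)."""
    if factor == 1:
        return channel
    return block_reduce(channel.astype(float), (factor, factor), np.mean)


def estimate_global_shift(
    he,
    ck,
    downsample: int = 32,
    basis: StainBasis | None = None,
    block_size: int = 151,
    offset: float = 10.0,
    min_area: int = 200,
) -> ShiftVector:
    """Coarse whole-slide shift of CK onto H&E, expressed at level 0.

    Eosin (H&E) and DAB (CK) channels are extracted at ``downsample``-fold
    reduction, binarized with :func:`registration_mask`, and correlated; the
    mask parameters apply at the downsampled scale.
    """
    eos = _downsample_channel(eosin_channel_8bit(he, basis), downsample)
    dab = _downsample_channel(dab_channel_8bit(ck, basis), downsample)
    if eos.max() <= offset or dab.max() <= offset:
        raise DegenerateInputError("all-background slide: no stain signal above offset")
    mask_he = registration_mask(eos, block_size, offset, min_area)
    mask_ck = registration_mask(dab, block_size, offset, min_area)
    if not mask_he.any() or not mask_ck.any():
        raise DegenerateInputError("all-background slide at requested downsample")
    s = shift_from_cross_correlation(mask_he, mask_ck)
    return ShiftVector(s.drow * downsample, s.dcol * downsample, 1)


def _crop_with_fill(img: np.ndarray, r0: int, c0: int, h: int, w: int, fill: int = 255) -> np.ndarray:
    """Crop ``img[r0:r0+h, c0:c0+w]``, padding out-of-bounds area with fill."""
    out = np.full((h, w) + img.shape[2:], fill, dtype=img.dtype)
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + h, img.shape[0]), min(c0 + w, img.shape[1])
    if re > rs and ce > cs:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = img[rs:re, cs:ce]
    return out


def estimate_local_shifts(
    he,
    ck,
    global_shift: ShiftVector,
    region_size: int = 10240,
    patch_size: int = 1024,
    basis: StainBasis | None = None,
    block_size: int = 151,
    offset: float = 10.0,
    min_area: int = 200,
    mad_factor: float = 3.0,
    mad_floor: float = 1.0,
) -> LocalShiftMap:
    """Per-region residual shifts refining ``global_shift``.

    The slide is gridded into ``region_size`` squares (partial edge regions
    kept at natural size).  Within a region, CK content is first brought into
    the H&E frame by ``global_shift``; residual shifts are measured per
    ``patch_size`` tile on binarized stain channels, near-white H&E patches
    are skipped, and patch shifts whose row or column component deviates from
    the region median by more than ``mad_factor`` x MAD (MAD floored at
    ``mad_floor`` px) are discarded as outliers.  The region's final shift is
    the rounded inlier mean plus the global shift; regions without usable
    patches inherit the global shift alone.
    """
    if region_size <= 0 or patch_size <= 0 or region_size % patch_size != 0:
        raise ValueError("region_size must be a positive multiple of patch_size")
    he_px = he.pixels if isinstance(he, RGBImage) else np.asarray(he)
    ck_px = ck.pixels if isinstance(ck, RGBImage) else np.asarray(ck)
    H, W = he_px.shape[:2]
    gr, gc = global_shift.drow, global_shift.dcol
    result = LocalShiftMap(region_size=region_size)

    for r0 in range(0, H, region_size):
        for c0 in range(0, W, region_size):
            rh = min(region_size, H - r0)
            rw = min(region_size, W - c0)
            he_region = he_px[r0 : r0 + rh, c0 : c0 + rw]
            # CK displaced by (gr, gc) relative to H&E: realign by sampling at +shift
            ck_region = _crop_with_fill(ck_px, r0 + gr, c0 + gc, rh, rw)
            shifts: list[tuple[int, int]] = []
            for pr in range(0, rh - patch_size + 1, patch_size):
                for pc in range(0, rw - patch_size + 1, patch_size):
                    he_patch = he_region[pr : pr + patch_size, pc : pc + patch_size]
                    if is_white_background(he_patch):
                        continue
                    ck_patch = ck_region[pr : pr + patch_size, pc : pc + patch_size]
                    try:
                        m_he = registration_mask(
                            eosin_channel_8bit(he_patch, basis), block_size, offset, min_area
                        )
                        m_ck = registration_mask(
                            dab_channel_8bit(ck_patch, basis), block_size, offset, min_area
                        )
                        s = shift_from_cross_correlation(m_he, m_ck)
                    except DegenerateInputError:
                        continue
                    shifts.append((s.drow, s.dcol))
            if shifts:
                arr = np.asarray(shifts, dtype=float)
                med = np.median(arr, axis=0)
                mad = np.maximum(np.median(np.abs(arr - med), axis=0), mad_floor)
                inlier = np.all(np.abs(arr - med) <= mad_factor * mad, axis=1)
                mean = arr[inlier].mean(axis=0)
                final = ShiftVector(int(round(mean[0])) + gr, int(round(mean[1])) + gc, 1)
                n_in = int(inlier.sum())
            else:
                final = ShiftVector(gr, gc, 1)
                n_in = 0
            result.entries.append(((r0, c0), final))
            result.inlier_counts[(r0, c0)] = n_in
    return result
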