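"""Tumor-stroma ratio scoring from an H&E image and its virtual CK image.

Tissue is segmented from the H&E image (grayscale < 200), tumor from the
virtual CK image (8-bit DAB channel > 80), and stroma is tissue minus tumor.
The score is

    dTSR = stroma_area / (tumor_area + stroma_area) * 100 %

computed per pathologist-annotated hotspot; the slide score is the
unweighted mean over hotspots and is dichotomized at a cut-off
(default 65 %, strictly greater = dTSR-high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .patchflow import grayscale_luma
from .stains import RGBImage, StainBasis, dab_channel_8bit
from .virtual_stain import ModelState, generate_and_stitch

__all__ = [
    "MaskSet",
    "TSRScore",
    "HotspotAnnotation",
    "UndefinedScoreError",
    "tissue_mask",
    "tumor_mask",
    "compute_dtsr",
    "score_wsi",
]


class UndefinedScoreError(ValueError):
    """Raised when a score is requested on a tissue-free field."""


@dataclass
class MaskSet:
    """Tissue / tumor / stroma binary masks with the set-algebra invariants."""

    tissue: np.ndarray
    tumor: np.ndarray
    stroma: np.ndarray

    def __post_init__(self) -> None:
        if not (self.tissue.shape == self.tumor.shape == self.stroma.shape):
            raise ValueError("masks must share a shape")


@dataclass
class TSRScore:
    tumor_area: int
    stroma_area: int
    dtsr: float
    tsr_class: str  # "dTSR-low" | "dTSR-high"
    hotspot_scores: list[float] = field(default_factory=list)


@dataclass
class HotspotAnnotation:
    """Closed polygons in 0-based level-0 (row, col) pixel coordinates."""

    polygons: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.polygons:
            raise ValueError("at least one hotspot polygon required")
        self.polygons = [np.asarray(p, dtype=float) for p in self.polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (row, col) vertices")


def tissue_mask(he_image, gray_threshold: int = 200) -> np.ndarray:
    """Tissue = pixels with ITU-R 601 grayscale strictly below the threshold."""
    px = he_image.pixels if isinstance(he_image, RGBImage) else np.asarray(he_image)
    return grayscale_luma(px) < gray_threshold


def tumor_mask(virtual_ck, dab_threshold: int = 80, basis: StainBasis | None = None) -> np.ndarray:
    """Tumor = pixels whose 8-bit DAB channel strictly exceeds the threshold."""
    px = virtual_ck.pixels if isinstance(virtual_ck, RGBImage) else np.asarray(virtual_ck)
    return dab_channel_8bit(px, basis) > dab_threshold


def build_masks(he_image, virtual_ck, gray_threshold: int = 200, dab_threshold: int = 80) -> MaskSet:
    tissue = tissue_mask(he_image, gray_threshold)
    tumor = tumor_mask(virtual_ck, dab_threshold) & tissue  # conserve areas within tissue
    return MaskSet(tissue=tissue, tumor=tumor, stroma=tissue & ~tumor)


def compute_dtsr(he_image, virtual_ck, gray_threshold: int = 200, dab_threshold: int = 80) -> TSRScore:
    """Score one field: stroma share of the tissue area, in percent."""
    he_px = he_image.pixels if isinstance(he_image, RGBImage) else np.asarray(he_image)
    ck_px = virtual_ck.pixels if isinstance(virtual_ck, RGBImage) else np.asarray(virtual_ck)
    if he_px.shape != ck_px.shape:
        raise ValueError("H&E and CK images must share a shape")
    masks = build_masks(he_px, ck_px, gray_threshold, dab_threshold)
    tumor_area = int(masks.tumor.sum())
    stroma_area = int(masks.stroma.sum())
    if tumor_area + stroma_area == 0:
        raise UndefinedScoreError("no tissue in field")
    dtsr = 100.0 * stroma_area / (tumor_area + stroma_area)
    return TSRScore(tumor_area, stroma_area, dtsr, "", [])


def classify(dtsr: float, cutoff: float = 65.0) -> str:
    return "dTSR-high" if dtsr > cutoff else "dTSR-low"


def score_wsi(
    he_wsi,
    model_state,
    hotspots: HotspotAnnotation,
    cutoff: float = 65.0,
    tile: int = 256,
    gray_threshold: int = 200,
    dab_threshold: int = 80,
) -> TSRScore:
    """Average hotspot dTSR over a slide and dichotomize at the cut-off.

    Each hotspot's bounding box is cropped, virtually stained (``model_state``
    may be a trained :class:`~virtualck.virtual_stain.ModelState` or any
    object with a ``virtual_ck(region) -> HxWx3 uint8`` method, e.g. an
    oracle), pixels outside the polygon are whitened to background, and the
    field is scored.  Hotspots without tissue raise; the slide score is the
    unweighted mean of the per-hotspot scores.
    """
    he_px = he_wsi.pixels if isinstance(he_wsi, RGBImage) else np.asarray(he_wsi)
    scores: list[float] = []
    tumor_total = stroma_total = 0
    for poly in hotspots.polygons:
        r0 = max(int(np.floor(poly[:, 0].min())), 0)
        c0 = max(int(np.floor(poly[:, 1].min())), 0)
        r1 = min(int(np.ceil(poly[:, 0].max())) + 1, he_px.shape[0])
        c1 = min(int(np.ceil(poly[:, 1].max())) + 1, he_px.shape[1])
        crop = he_px[r0:r1, c0:c1]
        inside = polygon2mask(crop.shape[:2], poly - [r0, c0])
        he_field = np.where(inside[..., None], crop, 255).astype(np.uint8)
        if isinstance(model_state, ModelState):
            h = (crop.shape[0] // tile) * tile
            w = (crop.shape[1] // tile) * tile
            if h == 0 or w == 0:
                # pad small hotspots up to one tile with white
                padded = np.full((max(h, tile), max(w, tile), 3), 255, dtype=np.uint8)
                padded[: crop.shape[0], : crop.shape[1]] = he_field
                ck_field = generate_and_stitch(padded, model_state, tile).pixels[
                    : crop.shape[0], : crop.shape[1]
                ]
            else:
                ck_field = generate_and_stitch(he_field, model_state, tile).pixels
        elif hasattr(model_state, "virtual_ck_at"):
            ck_field = np.asarray(model_state.virtual_ck_at(r0, c0, r1, c1))
        else:
            ck_field = np.asarray(model_state.virtual_ck(he_field))
        ck_field = np.where(inside[..., None], ck_field[: crop.shape[0], : crop.shape[1]], 255).astype(np.uint8)
        frag = compute_dtsr(he_field, ck_field, gray_threshold, dab_threshold)
        scores.append(frag.dtsr)
        tumor_total += frag.tumor_area
        stroma_total += frag.stroma_area
    mean = float(np.mean(scores))
    return TSRScore(
        tumor_area=tumor_total,
        stroma_area=stroma_total,
        dtsr=mean,
        tsr_class=classify(mean, cutoff),
        hotspot_scores=scores,
    )
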