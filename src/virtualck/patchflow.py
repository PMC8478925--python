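"""Tiling of registered slide pairs into training patches, plus curation.

Two filters mirror how paired histology patches are curated in practice:
near-white H&E patches carry no tissue and are dropped outright, and CK
patches with almost no DAB signal ("little dyed", no epithelial cells) are
down-sampled to a small fixed share of the training set so the generator
still sees negative examples without being swamped by them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import stains

__all__ = [
    "PatchPair",
    "PairedPatchDataset",
    "tile_pairs",
    "grayscale_luma",
    "is_white_background",
    "is_little_dyed",
    "assemble_training_set",
]


@dataclass
class PatchPair:
    """A registered (H&E, CK) patch pair with its level-0 tile origin."""

    he: np.ndarray
    ck: np.ndarray
    origin: tuple[int, int] = (0, 0)
    white_background: bool = False
    little_dyed: bool = False

    def __post_init__(self) -> None:
        if self.he.shape != self.ck.shape:
            raise ValueError("paired patches must share a shape")


@dataclass
class PairedPatchDataset:
    """Curated, ordered training pairs plus provenance for reproducibility."""

    pairs: list[PatchPair]
    slide_id: str = ""
    registration_id: str = ""
    seed: int | None = None
    little_dyed_fraction: float = 0.10


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, stains.RGBImage) else np.asarray(img)


def tile_pairs(he_region, ck_region, tile: int = 256, origin: tuple[int, int] = (0, 0)) -> list[PatchPair]:
    """Cut two aligned regions into a disjoint grid of ``tile`` x ``tile`` pairs.

    Partial edge tiles are dropped; a region smaller than one tile yields an
    empty list.  Origins are 0-based level-0 coordinates offset by ``origin``.
    """
    he_px, ck_px = _pixels(he_region), _pixels(ck_region)
    if he_px.shape != ck_px.shape:
        raise ValueError("regions must have identical shape")
    H, W = he_px.shape[:2]
    out = []
    for r in range(0, H - tile + 1, tile):
        for c in range(0, W - tile + 1, tile):
            out.append(
                PatchPair(
                    he=he_px[r : r + tile, c : c + tile],
                    ck=ck_px[r : r + tile, c : c + tile],
                    origin=(origin[0] + r, origin[1] + c),
                )
            )
    return out


def grayscale_luma(rgb: np.ndarray) -> np.ndarray:
    """ITU-R 601 luma of an 8-bit RGB array, rounded to integers."""
    px = np.asarray(rgb, dtype=float)
    return np.rint(0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2])


def is_white_background(he_patch, threshold: int = 220, fraction: float = 0.95) -> bool:
    """True iff strictly more than ``fraction`` of grayscale pixels exceed ``threshold``."""
    gray = grayscale_luma(_pixels(he_patch))
    return float(np.mean(gray > threshold)) > fraction


def is_little_dyed(
    ck_patch,
    dab_threshold: int = 80,
    fraction: float = 0.05,
    basis: stains.StainBasis | None = None,
) -> bool:
    """True iff strictly less than ``fraction`` of pixels have 8-bit DAB > ``dab_threshold``."""
    dab = stains.dab_channel_8bit(_pixels(ck_patch), basis)
    return float(np.mean(dab > dab_threshold)) < fraction


def assemble_training_set(
    pairs: list[PatchPair],
    little_dyed_fraction: float = 0.10,
    seed: int = 0,
) -> PairedPatchDataset:
    """Apply both curation filters and rebalance little-dyed pairs.

    White-background pairs are removed.  Little-dyed pairs are subsampled
    uniformly at random (without replacement, seeded) down to
    ``k = round(f / (1 - f) * n_informative)`` so they form as close as
    possible to fraction ``f`` of the final set.  Original order is kept.
    """
    if not 0 <= little_dyed_fraction <= 1:
        raise ValueError("little_dyed_fraction must lie in [0, 1]")
    kept = []
    for p in pairs:
        p.white_background = is_white_background(p.he)
        if p.white_background:
            continue
        p.little_dyed = is_little_dyed(p.ck)
        kept.append(p)
    dyed_idx = [i for i, p in enumerate(kept) if p.little_dyed]
    n_inf = len(kept) - len(dyed_idx)
    if dyed_idx and little_dyed_fraction < 1:
        k = int(round(little_dyed_fraction / (1 - little_dyed_fraction) * n_inf))
        k = min(k, len(dyed_idx))
        rng = np.random.default_rng(seed)
        selected = set(rng.choice(len(dyed_idx), size=k, replace=False).tolist()) if k else set()
        drop = {dyed_idx[i] for i in range(len(dyed_idx)) if i not in selected}
        kept = [p for i, p in enumerate(kept) if i not in drop]
    return PairedPatchDataset(pairs=kept, seed=seed, little_dyed_fraction=little_dyed_fraction)
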