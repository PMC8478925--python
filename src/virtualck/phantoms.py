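"""Synthetic paired pseudo-H&E / pseudo-CK slides with exact ground truth.

No raster data ships with the package, so every downstream stage is
exercised on phantoms: a disc-shaped tissue region containing a compact
tumor of prescribed area fraction, sprinkled with gland-lumen-like pale
blobs that give the stain channels the spatial texture real sections have
(and that adaptive-threshold registration masks need).  Rasters are rendered
through the same Beer-Lambert forward model the deconvolution inverts, with
hard-edged geometry (no anti-aliasing) so area accounting is exact, optional
additive Gaussian noise (clamped, truth defined pre-noise), and full
determinism under a seed.

What these phantoms do not emulate: cellular texture, staining gradients,
scanner artifacts, or any non-rigid deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registration import ShiftVector
from .stains import RGBImage, StainBasis, stain_to_rgb
from .tsr import HotspotAnnotation

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom_pair",
    "make_shifted_pair",
    "generate_benchmark",
    "OracleCKProvider",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, stain chemistry and noise of one phantom slide pair.

    ``tumor_fraction`` is the target tumor share of the tissue area (the
    remainder, minus nothing else, is stroma).  ``lumen_density`` controls
    the pale texture blobs per unit tissue area; their radii are drawn
    uniformly from ``lumen_radius`` (pixels).  Stain concentrations are in
    OD units of the Beer-Lambert renderer.
    """

    size: int = 512
    tissue_radius_frac: float = 0.44
    tumor_fraction: float = 0.5
    lumen_density: float = 6e-4
    lumen_radius: tuple[int, int] = (6, 14)
    speckle_density: float = 8e-3
    speckle_radius: tuple[int, int] = (1, 3)
    # (hematoxylin, eosin) in the H&E render
    he_stroma: tuple[float, float] = (0.25, 0.5)
    he_tumor: tuple[float, float] = (0.6, 0.3)
    he_lumen: tuple[float, float] = (0.15, 0.1)
    # CK render: hematoxylin counterstain + DAB in tumor
    ck_counterstain: float = 0.25
    ck_lumen_h: float = 0.15
    ck_dab: float = 0.9
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        for v in self.he_stroma + self.he_tumor + self.he_lumen + (self.ck_counterstain, self.ck_dab):
            if v < 0:
                raise ValueError("stain concentrations must be non-negative")


@dataclass
class PhantomTruth:
    """Exact pre-noise geometry of a rendered phantom."""

    tissue: np.ndarray
    tumor: np.ndarray
    planted_shift: ShiftVector = field(default_factory=lambda: ShiftVector(0, 0))

    @property
    def stroma_fraction(self) -> float:
        """True stroma percentage of the tissue area."""
        n_tissue = int(self.tissue.sum())
        return 100.0 * (n_tissue - int(self.tumor.sum())) / n_tissue


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _paint_disc(mask: np.ndarray, center, radius: int) -> None:
    """Set a filled disc in-place, touching only its bounding window."""
    r, c = int(center[0]), int(center[1])
    rad = int(radius)
    r0, r1 = max(r - rad, 0), min(r + rad + 1, mask.shape[0])
    c0, c1 = max(c - rad, 0), min(c + rad + 1, mask.shape[1])
    rr, cc = np.ogrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2


def render_phantom_pair(spec: PhantomSpec, basis: StainBasis | None = None):
    """Render one (H&E, CK) pair and its exact truth masks.

    The tumor is grown from the tissue center pixel-by-pixel in order of
    distance, counting only non-lumen pixels toward the target area, so the
    true tumor fraction hits ``round(tumor_fraction * |tissue|)`` exactly.
    """
    basis = basis or StainBasis()
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    center = (n // 2, n // 2)
    tissue = _disc_mask((n, n), center, spec.tissue_radius_frac * n)

    # pale lumen-like texture at two scales: gland-size blobs that survive
    # coarse downsampling, plus nuclei-scale speckle that sharpens the
    # patch-level correlation peak
    lumen = np.zeros((n, n), dtype=bool)
    rows, cols = np.nonzero(tissue)
    for density, (rmin, rmax) in (
        (spec.lumen_density, spec.lumen_radius),
        (spec.speckle_density, spec.speckle_radius),
    ):
        n_blobs = rng.poisson(density * tissue.sum())
        if n_blobs and rows.size:
            pick = rng.integers(0, rows.size, size=n_blobs)
            radii = rng.integers(rmin, rmax + 1, size=n_blobs)
            for (r, c), rad in zip(zip(rows[pick], cols[pick]), radii):
                _paint_disc(lumen, (r, c), rad)
    lumen &= tissue

    # grow the tumor outward from the center over tissue pixels
    target = int(round(spec.tumor_fraction * tissue.sum()))
    dist2 = (rows - center[0]) ** 2 + (cols - center[1]) ** 2
    order = np.lexsort((cols, rows, dist2))
    non_lumen = ~lumen[rows[order], cols[order]]
    cum = np.cumsum(non_lumen)
    m = int(np.searchsorted(cum, target)) + 1 if target > 0 else 0
    region = np.zeros((n, n), dtype=bool)
    if m:
        sel = order[: min(m, order.size)]
        region[rows[sel], cols[sel]] = True
    tumor = region & ~lumen

    he_conc = np.zeros((n, n, 3))
    stroma = tissue & ~tumor & ~lumen
    he_conc[stroma] = (*spec.he_stroma, 0.0)
    he_conc[tumor] = (*spec.he_tumor, 0.0)
    he_conc[lumen] = (*spec.he_lumen, 0.0)

    ck_conc = np.zeros((n, n, 3))
    ck_conc[tissue & ~lumen, 0] = spec.ck_counterstain
    ck_conc[lumen, 0] = spec.ck_lumen_h
    ck_conc[tumor, 2] = spec.ck_dab

    he = stain_to_rgb(he_conc, basis).pixels
    ck = stain_to_rgb(ck_conc, basis).pixels
    if spec.noise_sd > 0:
        he = _add_noise(he, spec.noise_sd, np.random.default_rng(spec.seed + 1))
        ck = _add_noise(ck, spec.noise_sd, np.random.default_rng(spec.seed + 2))
    return RGBImage(he), RGBImage(ck), PhantomTruth(tissue=tissue, tumor=tumor)


def _add_noise(px: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    noisy = px.astype(float) + rng.normal(0.0, sd, px.shape)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def make_shifted_pair(pair, shift: ShiftVector):
    """Translate the CK raster by ``shift`` (white fill at exposed margins)."""
    he, ck, truth = pair
    ck_px = ck.pixels if isinstance(ck, RGBImage) else np.asarray(ck)
    H, W = ck_px.shape[:2]
    if abs(shift.drow) >= H // 4 or abs(shift.dcol) >= W // 4:
        raise ValueError("planted shift too large: content overlap lost")
    out = np.full_like(ck_px, 255)
    dr, dc = shift.drow, shift.dcol
    rs, cs = max(dr, 0), max(dc, 0)
    re, ce = min(H + dr, H), min(W + dc, W)
    out[rs:re, cs:ce] = ck_px[rs - dr : re - dr, cs - dc : ce - dc]
    new_truth = PhantomTruth(tissue=truth.tissue, tumor=truth.tumor, planted_shift=shift)
    return he, RGBImage(out), new_truth


@dataclass
class OracleCKProvider:
    """Serves crops of a known-good CK raster to the scoring path.

    Stands in for a trained generator when the test needs the scoring
    arithmetic isolated from model quality.
    """

    ck: np.ndarray

    def virtual_ck_at(self, r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
        return self.ck[r0:r1, c0:c1]


@dataclass
class BenchmarkSlide:
    slide_id: str
    he: RGBImage
    ck: RGBImage
    truth: PhantomTruth
    hotspots: HotspotAnnotation
    oracle: OracleCKProvider


def _tissue_bbox_polygon(tissue: np.ndarray) -> np.ndarray:
    rows = np.nonzero(tissue.any(axis=1))[0]
    cols = np.nonzero(tissue.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    return np.array([[r0, c0], [r0, c1 + 1], [r1 + 1, c1 + 1], [r1 + 1, c0]], dtype=float)


def generate_benchmark(
    n_slides: int,
    stroma_fractions,
    template: PhantomSpec | None = None,
    seed: int = 0,
    cutoff: float = 65.0,
):
    """A phantom cohort standing in for a slide test set.

    One phantom per requested true stroma fraction (cycled to ``n_slides``),
    each with a hotspot polygon covering its tissue.  Returns the slide list
    and a truth table (slide_id, true stroma fraction, true class at the
    cut-off).
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    template = template or PhantomSpec()
    fractions = list(stroma_fractions)
    slides: list[BenchmarkSlide] = []
    records = []
    for i in range(n_slides):
        sf = fractions[i % len(fractions)]
        spec = replace(template, tumor_fraction=1.0 - sf / 100.0, seed=seed + 1000 * i)
        he, ck, truth = render_phantom_pair(spec)
        hotspots = HotspotAnnotation([_tissue_bbox_polygon(truth.tissue)])
        sid = f"phantom-{i:03d}"
        slides.append(BenchmarkSlide(sid, he, ck, truth, hotspots, OracleCKProvider(ck.pixels)))
        records.append(
            {
                "slide_id": sid,
                "true_stroma_fraction": truth.stroma_fraction,
                "true_class": "dTSR-high" if truth.stroma_fraction > cutoff else "dTSR-low",
            }
        )
    return slides, pd.DataFrame.from_records(records)
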