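"""Color deconvolution between RGB and H/E/DAB stain-concentration space.

Brightfield histology obeys Beer-Lambert absorption: the optical density
``OD_c = -log10(I_c / I_0)`` of each RGB channel is (to first order) a linear
mixture of per-stain concentrations, with mixing weights given by each
stain's characteristic absorption vector.  Inverting that 3x3 linear system
("color deconvolution", Ruifrok & Johnston 2001) separates hematoxylin,
eosin and DAB contributions, which downstream stages use for registration
masks, patch curation, the stain-space L1 training loss, and tumor masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainBasis",
    "RGBImage",
    "StainConcentrationImage",
    "rgb_to_stain",
    "stain_to_rgb",
    "stain_channel_to_8bit",
    "CHANNEL_INDEX",
]

#: Ruifrok-Johnston absorption vectors for hematoxylin, eosin and DAB,
#: rows in R,G,B optical-density units (unnormalized literature values).
RUIFROK_JOHNSTON_HED = np.array(
    [
        [0.65, 0.70, 0.29],  # hematoxylin
        [0.07, 0.99, 0.11],  # eosin
        [0.27, 0.57, 0.78],  # DAB
    ]
)

CHANNEL_INDEX = {"H": 0, "E": 1, "DAB": 2}


class InvalidStainBasisError(ValueError):
    """Raised when a stain matrix is singular or otherwise unusable."""


@dataclass(frozen=True)
class StainBasis:
    """A 3x3 optical-density stain matrix (rows: H, E, DAB; columns R, G, B).

    Rows are normalized to unit Euclidean length on construction.  The matrix
    must be invertible: deconvolution solves ``OD = conc @ matrix`` for the
    concentrations.
    """

    matrix: np.ndarray = field(default_factory=lambda: RUIFROK_JOHNSTON_HED.copy())

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise InvalidStainBasisError(f"stain matrix must be 3x3, got {m.shape}")
        if np.any(m < 0):
            raise InvalidStainBasisError("stain vectors must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise InvalidStainBasisError("stain vector with zero norm")
        m = m / norms[:, None]
        if abs(np.linalg.det(m)) < 1e-8:
            raise InvalidStainBasisError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    @classmethod
    def from_flat(cls, values) -> "StainBasis":
        """Build from a row-major list of 9 numbers (config convenience)."""
        arr = np.asarray(list(values), dtype=float)
        if arr.size != 9:
            raise InvalidStainBasisError("expected 9 numbers (row-major 3x3)")
        return cls(arr.reshape(3, 3))


@dataclass
class RGBImage:
    """An 8-bit RGB raster plus minimal slide metadata.

    ``pixel_size`` is in micrometres per pixel; ``level`` identifies the
    pyramid level the raster was read from (0 = full resolution).
    """

    pixels: np.ndarray
    pixel_size: float = 0.32
    level: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class StainConcentrationImage:
    """Per-pixel stain concentrations, channels ordered (H, E, DAB), OD units."""

    concentrations: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError(f"expected HxWx3 array, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite")
        self.concentrations = c

    def channel(self, name: str) -> np.ndarray:
        return self.concentrations[..., CHANNEL_INDEX[name]]


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, RGBImage):
        return image.pixels
    return np.asarray(image)


def rgb_to_stain(image, basis: StainBasis | None = None, eps: float = 1.0) -> StainConcentrationImage:
    """Deconvolve an RGB image into H/E/DAB concentrations.

    Optical density is ``-log10((v + eps) / 255)`` per channel; ``eps`` keeps
    the log finite at value 0.  Concentrations are ``OD @ inv(basis)`` with
    negative solutions clamped to zero (out-of-gamut colors).
    """
    basis = basis or StainBasis()
    px = _as_pixels(image).astype(float)
    od = -np.log10((px + eps) / 255.0)
    conc = od @ basis.inverse
    np.clip(conc, 0.0, None, out=conc)
    return StainConcentrationImage(conc)


def stain_to_rgb(conc, basis: StainBasis | None = None) -> RGBImage:
    """Render concentrations back to 8-bit RGB through Beer-Lambert absorption.

    Inverse of :func:`rgb_to_stain` up to 8-bit quantization:
    ``v_c = round(255 * 10**(-(conc @ basis)_c))``.
    """
    basis = basis or StainBasis()
    c = conc.concentrations if isinstance(conc, StainConcentrationImage) else np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("stain concentrations must be non-negative")
    od = c @ basis.matrix
    v = np.rint(255.0 * np.power(10.0, -od))
    return RGBImage(np.clip(v, 0, 255).astype(np.uint8))


def stain_channel_to_8bit(conc: StainConcentrationImage, channel: str, c_max: float = 1.0) -> np.ndarray:
    """Map one stain channel to an 8-bit raster (0 = no stain, 255 = c_max).

    Concentration ``c_max`` and above saturate at 255; the mapping is linear
    and monotone below that.  The default ``c_max = 1.0`` places the
    pipeline's DAB threshold of 80 at concentration ~0.314.
    """
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    ch = conc.channel(channel) if isinstance(conc, StainConcentrationImage) else np.asarray(conc)[..., CHANNEL_INDEX[channel]]
    scaled = np.rint(255.0 * np.minimum(ch / c_max, 1.0))
    return scaled.astype(np.uint8)


def dab_channel_8bit(image, basis: StainBasis | None = None, c_max: float = 1.0) -> np.ndarray:
    """Convenience: RGB image -> 8-bit DAB channel map."""
    return stain_channel_to_8bit(rgb_to_stain(image, basis), "DAB", c_max)


def eosin_channel_8bit(image, basis: StainBasis | None = None, c_max: float = 1.0) -> np.ndarray:
    """Convenience: RGB image -> 8-bit eosin channel map."""
    return stain_channel_to_8bit(rgb_to_stain(image, basis), "E", c_max)
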