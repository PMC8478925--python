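"""Raster and annotation I/O: flat PNG/TIFF images, hotspot JSON, label CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .stains import RGBImage
from .tsr import HotspotAnnotation


def read_rgb(path, pixel_size: float = 0.32, level: int = 0) -> RGBImage:
    """Read an 8-bit RGB raster from PNG or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return RGBImage(arr[..., :3], pixel_size=pixel_size, level=level)


def write_rgb(image, path) -> None:
    px = image.pixels if isinstance(image, RGBImage) else np.asarray(image)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px, photometric="rgb")
    else:
        Image.fromarray(px).save(path)


def read_hotspots(path) -> HotspotAnnotation:
    """Hotspot JSON: a list of polygons, each a list of [row, col] vertices."""
    with open(path) as fh:
        data = json.load(fh)
    polys = data["polygons"] if isinstance(data, dict) else data
    return HotspotAnnotation([np.asarray(p, dtype=float) for p in polys])


def write_hotspots(annotation: HotspotAnnotation, path) -> None:
    with open(path, "w") as fh:
        json.dump({"polygons": [p.tolist() for p in annotation.polygons]}, fh)
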