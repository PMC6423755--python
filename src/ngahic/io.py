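"""File I/O: spot images (PNG/TIFF), 16-bit label masks (TIFF), and the
per-nucleus / per-spot CSV tables."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import DEFAULT_MICRONS_PER_PIXEL, NuclearMask, NucleusRecord, SpotImage


def read_spot_image(path: str | Path, microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL) -> SpotImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    return SpotImage(pixels=px, microns_per_pixel=microns_per_pixel)


def write_spot_image(path: str | Path, image: SpotImage) -> None:
    path = Path(path)
    px = np.asarray(image.pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def read_mask(path: str | Path) -> NuclearMask:
    return NuclearMask(tifffile.imread(Path(path)).astype(np.int32))


def write_mask(path: str | Path, mask: NuclearMask) -> None:
    labels = mask.labels
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))


def nucleus_table(records: list[NucleusRecord]) -> pd.DataFrame:
    """Per-nucleus CSV table (label, centroid, area, perimeter, orientation,
    eccentricity)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "centroid_x": [r.centroid[0] for r in records],
            "centroid_y": [r.centroid[1] for r in records],
            "area_px2": [r.area for r in records],
            "perimeter_px": [r.perimeter for r in records],
            "orientation_deg": [r.orientation for r in records],
            "eccentricity": [r.eccentricity for r in records],
            "orientation_defined": [r.orientation_defined for r in records],
        }
    )


def write_features_csv(path: str | Path, features: pd.DataFrame) -> None:
    features.to_csv(Path(path))


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), index_col=0)
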