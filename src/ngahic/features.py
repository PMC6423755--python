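"""Assembly of the full 189-feature quantitative-histomorphometry vector.

Family sizes: shape 100, texture 30, orientation 39, Voronoi 12, Delaunay 8.
Feature names are stable, unique and ordered; the canonical order is
shape -> texture -> orientation -> voronoi -> delaunay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NuclearMask, SpotImage
from .graph_features import (
    DELAUNAY_ATTRS,
    DELAUNAY_STATS,
    K_NEIGHBORS,
    ORIENTATION_BINS,
    ORIENTATION_DESCRIPTOR_NAMES,
    ORIENTATION_STATS,
    VORONOI_ATTRS,
    VORONOI_STATS,
    delaunay_features,
    orientation_features,
    voronoi_features,
)
from .segment import extract_nucleus_records, segment_nuclei
from .shape_features import AGGREGATE_STATS, SHAPE_DESCRIPTOR_NAMES, aggregate_shape, shape_descriptors
from .stains import color_deconvolve
from .texture_features import CHANNEL_NAMES, TEXTURE_DESCRIPTOR_NAMES, texture_features

FAMILY_SIZES = {"shape": 100, "texture": 30, "orientation": 39, "voronoi": 12, "delaunay": 8}
N_FEATURES_TOTAL = 189


def family_names(family: str) -> list[str]:
    if family == "shape":
        return [f"shape:{d}:{s}" for d in SHAPE_DESCRIPTOR_NAMES for s in AGGREGATE_STATS]
    if family == "texture":
        return [
            f"texture:{d}:{ch}:{s}"
            for d in TEXTURE_DESCRIPTOR_NAMES
            for ch in CHANNEL_NAMES
            for s in ("mean", "sd")
        ]
    if family == "orientation":
        return [f"orient:{d}:{s}" for d in ORIENTATION_DESCRIPTOR_NAMES for s in ORIENTATION_STATS]
    if family == "voronoi":
        return [f"voronoi:{a}:{s}" for a in VORONOI_ATTRS for s in VORONOI_STATS]
    if family == "delaunay":
        return [f"delaunay:{a}:{s}" for a in DELAUNAY_ATTRS for s in DELAUNAY_STATS]
    raise KeyError(f"unknown feature family {family!r}")


def feature_names() -> list[str]:
    """The canonical ordered 189 feature names."""
    names: list[str] = []
    for fam in ("shape", "texture", "orientation", "voronoi", "delaunay"):
        names.extend(family_names(fam))
    return names


@dataclass
class SpotFeatureVector:
    """The named 189-value feature vector of one TMA spot."""

    spot_id: str
    values: pd.Series  # index = canonical feature names

    def __len__(self) -> int:
        return len(self.values)


def assemble_feature_vector(
    shape: dict[str, float],
    texture: dict[str, float],
    orientation: dict[str, float],
    voronoi: dict[str, float],
    delaunay: dict[str, float],
    spot_id: str = "spot",
) -> SpotFeatureVector:
    """Concatenate the five families into the canonical 189-feature vector.

    Raises when any family has the wrong length or wrong names.
    """
    families = {
        "shape": shape,
        "texture": texture,
        "orientation": orientation,
        "voronoi": voronoi,
        "delaunay": delaunay,
    }
    values: dict[str, float] = {}
    for fam, d in families.items():
        expected = FAMILY_SIZES[fam]
        if len(d) != expected:
            raise ValueError(f"family {fam} expected {expected}, got {len(d)}")
        names = family_names(fam)
        missing = set(names) - set(d)
        if missing:
            raise ValueError(f"family {fam} missing features: {sorted(missing)[:3]}...")
        for name in names:
            values[name] = float(d[name])
    series = pd.Series(values, index=feature_names(), dtype=float)
    assert len(series) == N_FEATURES_TOTAL
    return SpotFeatureVector(spot_id=spot_id, values=series)


def extract_spot_features(
    image: SpotImage,
    mask: NuclearMask | None = None,
    spot_id: str = "spot",
    k_neighbors: int = K_NEIGHBORS,
    orientation_bins: int = ORIENTATION_BINS,
) -> SpotFeatureVector:
    """Full extraction for one spot: deconvolve, segment (unless a mask is
    supplied), and compute all five feature families."""
    if mask is None:
        hema, _, _ = color_deconvolve(image.pixels)
        mask = segment_nuclei(hema)
    records = extract_nucleus_records(mask, image)
    if len(records) < max(4, k_neighbors + 1):
        raise ValueError(f"too few nuclei ({len(records)}) for feature extraction")
    shape = aggregate_shape([shape_descriptors(r) for r in records])
    texture = texture_features(records, image)
    orientation = orientation_features(records, k_neighbors=k_neighbors, n_bins=orientation_bins)
    centroids = np.array([r.centroid for r in records])
    h, w = image.shape
    voronoi = voronoi_features(centroids, bbox=(0.0, 0.0, float(w), float(h)))
    delaunay = delaunay_features(centroids)
    return assemble_feature_vector(shape, texture, orientation, voronoi, delaunay, spot_id=spot_id)
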