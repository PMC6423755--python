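"""Core data containers shared across the pipeline.

Coordinate convention: pixel-centered, ``x`` = column, ``y`` = row, origin at
the top-left corner of the raster.  Nuclear orientations are major-axis angles
in degrees, measured counter-clockwise from the +x axis and mapped to
``[0, 180)`` (an axis, not a direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: nominal scan resolution: 40x magnification, 0.25 micron per pixel
DEFAULT_MICRONS_PER_PIXEL = 0.25

#: Ki67 labeling index at or above this fraction of reactive tumor cells is
#: scored positive.
KI67_POSITIVE_CUTOFF = 0.14

#: eccentricity below which a nucleus is treated as circular: its orientation
#: is undefined, set to 0 deg by the tie-break rule and excluded from
#: orientation co-occurrence features.
CIRCULAR_ECCENTRICITY = 0.05


@dataclass
class SpotImage:
    """One RGB tissue-microarray spot raster with its physical pixel size."""

    pixels: np.ndarray  # H x W x 3, non-negative intensities
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("SpotImage requires an H x W x 3 raster")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("SpotImage requires H, W >= 64")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class NuclearMask:
    """Labeled segmentation raster: 0 = background, k > 0 = nucleus k."""

    labels: np.ndarray  # H x W integer raster

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("NuclearMask requires a 2-D label raster")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab

    @property
    def n_nuclei(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


@dataclass
class NucleusRecord:
    """One segmented nucleus and the per-nucleus quantities the feature
    families consume."""

    label: int
    centroid: tuple[float, float]  # (x, y) pixels
    boundary: np.ndarray  # closed simple polygon, N x 2 (x, y), N >= 8
    area: float  # px^2 (pixel count)
    perimeter: float  # px
    orientation: float  # degrees in [0, 180)
    eccentricity: float
    orientation_defined: bool
    per_channel_pixels: list[np.ndarray] = field(default_factory=list)
    #: intensity bounding-box patch (h x w x 3) and its interior mask, used by
    #: the nuclear texture family
    patch: np.ndarray | None = None
    patch_mask: np.ndarray | None = None
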