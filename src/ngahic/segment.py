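"""Watershed-based nuclear segmentation on the hematoxylin density channel.

Pipeline: Otsu threshold on the (lightly smoothed) hematoxylin raster ->
Euclidean distance transform -> smoothed local maxima as markers ->
marker-controlled watershed -> area filtering.  Touching nuclei are split at
the watershed lines between distance-transform peaks.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label as cc_label, regionprops
from skimage.segmentation import watershed

from .core import CIRCULAR_ECCENTRICITY, NuclearMask, NucleusRecord, SpotImage

log = logging.getLogger(__name__)

DEFAULT_MIN_AREA_PX = 30
DEFAULT_MAX_AREA_PX = 5000


def segment_nuclei(
    hema: np.ndarray,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
    max_area_px: int = DEFAULT_MAX_AREA_PX,
    smooth_sigma: float = 1.0,
    marker_sigma: float = 2.0,
    marker_min_distance: int = 7,
) -> NuclearMask:
    """Segment nuclei from a hematoxylin density raster.

    Returns a :class:`NuclearMask`; an image with no detectable foreground
    yields an empty mask (with a warning), not an error.
    """
    hema = np.asarray(hema, float)
    if hema.ndim != 2:
        raise ValueError("expected a 2-D density raster")
    labels = np.zeros(hema.shape, dtype=np.int32)
    smoothed = gaussian(hema, smooth_sigma, preserve_range=True) if smooth_sigma > 0 else hema
    if smoothed.max() - smoothed.min() <= 1e-12:
        log.warning("flat hematoxylin channel: no nuclei found")
        return NuclearMask(labels)
    thr = threshold_otsu(smoothed)
    binary = smoothed > thr
    if binary.sum() == 0:
        log.warning("empty foreground after thresholding")
        return NuclearMask(labels)
    binary = ndi.binary_fill_holes(binary)

    distance = ndi.distance_transform_edt(binary)
    dist_smooth = gaussian(distance, marker_sigma, preserve_range=True)
    components = cc_label(binary, connectivity=1)
    peaks = peak_local_max(
        dist_smooth,
        min_distance=marker_min_distance,
        labels=components,
        exclude_border=False,
    )
    if len(peaks) == 0:
        log.warning("no watershed markers found")
        return NuclearMask(labels)
    markers = np.zeros(hema.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    ws = watershed(-dist_smooth, markers, mask=binary, connectivity=1)

    # area filter and sequential relabeling
    out = np.zeros_like(ws, dtype=np.int32)
    next_label = 1
    for region in regionprops(ws):
        if min_area_px <= region.area <= max_area_px:
            out[ws == region.label] = next_label
            next_label += 1
    if next_label == 1:
        log.warning("all candidate objects removed by area filtering")
    return NuclearMask(out)


def _boundary_polygon(region) -> np.ndarray | None:
    """Closed (x, y) boundary polygon of one labeled region at sub-pixel
    0.5-level, in whole-image coordinates."""
    padded = np.pad(region.image.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    if len(contour) < 8:
        return None
    rows = contour[:, 0] - 1 + region.bbox[0]
    cols = contour[:, 1] - 1 + region.bbox[1]
    poly = np.column_stack([cols, rows])  # (x, y)
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def orientation_degrees(region) -> float:
    """Major-axis angle in degrees in [0, 180) measured from the +x (column)
    axis, from the second-moment ellipse fit."""
    return float((90.0 - np.degrees(region.orientation)) % 180.0)


def extract_nucleus_records(mask: NuclearMask, image: SpotImage) -> list[NucleusRecord]:
    """One :class:`NucleusRecord` per label; degenerate labels are dropped
    with a log entry.  Circular nuclei (eccentricity below the configured
    cut) get orientation 0 deg and are flagged undefined."""
    labels = mask.labels
    if labels.shape != image.shape:
        raise ValueError("mask and image dimensions differ")
    records: list[NucleusRecord] = []
    for region in regionprops(labels):
        poly = _boundary_polygon(region)
        if poly is None or region.area < 4:
            log.info("dropping degenerate label %d (area=%d)", region.label, region.area)
            continue
        ecc = float(region.eccentricity)
        defined = ecc >= CIRCULAR_ECCENTRICITY
        region_mask = labels == region.label
        channels = [image.pixels[region_mask][:, c].astype(float) for c in range(3)]
        closed = np.vstack([poly, poly[:1]])
        perimeter = float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())
        r0, c0, r1, c1 = region.bbox
        records.append(
            NucleusRecord(
                label=int(region.label),
                centroid=(float(region.centroid[1]), float(region.centroid[0])),
                boundary=poly,
                area=float(region.area),
                perimeter=perimeter,
                orientation=orientation_degrees(region) if defined else 0.0,
                eccentricity=ecc,
                orientation_defined=defined,
                per_channel_pixels=channels,
                patch=image.pixels[r0:r1, c0:c1].astype(float),
                patch_mask=region.image.copy(),
            )
        )
    return records
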