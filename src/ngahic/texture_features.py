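"""Nuclear texture features.

Per nucleus and per color channel, a gray-level co-occurrence matrix (GLCM:
8 levels, distance 1, symmetric, averaged over the four directions) is
computed over the nuclear interior only.  From it: contrast, energy
(angular second moment), entropy (bits) and inverse variance, plus the first
Hu invariant moment of the masked intensity patch.  Each descriptor is
aggregated across nuclei by {mean, SD} per channel, giving
5 descriptors x 3 channels x 2 statistics = 30 spot features.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.feature import graycomatrix
from skimage.measure import moments_central, moments_hu, moments_normalized

from .core import NucleusRecord, SpotImage

log = logging.getLogger(__name__)

GLCM_LEVELS = 8
GLCM_DISTANCE = 1
MIN_INTERIOR_PIXELS = 9

TEXTURE_DESCRIPTOR_NAMES = ("contrast", "energy", "entropy", "inverse_variance", "invariant_moment")
CHANNEL_NAMES = ("R", "G", "B")


def masked_glcm(channel_patch: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Normalized symmetric direction-averaged co-occurrence matrix over the
    masked interior of one intensity patch.

    Exterior pixels are assigned a sentinel level whose co-occurrence rows and
    columns are discarded, so only interior-interior pixel pairs contribute.
    Returns a ``levels x levels`` matrix summing to 1, or an empty (all-zero)
    matrix when no interior pair exists.
    """
    quant = np.minimum((np.asarray(channel_patch, float) / 256.0 * levels).astype(int), levels - 1)
    coded = np.where(mask, quant + 1, 0).astype(np.uint8)  # 0 = sentinel
    glcm = graycomatrix(
        coded,
        distances=[GLCM_DISTANCE],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
        normed=False,
    )
    counts = glcm[1:, 1:, 0, :].sum(axis=2).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_descriptors(P: np.ndarray) -> dict[str, float]:
    """Contrast, energy, entropy (bits), inverse variance from a normalized
    co-occurrence matrix."""
    levels = P.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    diff2 = (i - j) ** 2
    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum()) if nz.any() else 0.0
    off = diff2 > 0
    return {
        "contrast": float((P * diff2).sum()),
        "energy": float((P**2).sum()),
        "entropy": entropy,
        "inverse_variance": float((P[off] / diff2[off]).sum()),
    }


def _patch_invariant_moment(channel_patch: np.ndarray, mask: np.ndarray) -> float:
    """First Hu moment of the masked intensity patch."""
    weighted = np.where(mask, np.asarray(channel_patch, float), 0.0)
    if weighted.sum() <= 0:
        return 0.0
    mu = moments_central(weighted)
    return float(moments_hu(moments_normalized(mu))[0])


def texture_features(records: list[NucleusRecord], image: SpotImage | None = None) -> dict[str, float]:
    """The 30 spot-level texture features ``texture:<descriptor>:<channel>:<stat>``.

    ``image`` is accepted for interface symmetry; the per-nucleus intensity
    patches carried by the records are used directly.
    """
    per_channel: dict[tuple[str, str], list[float]] = {
        (d, ch): [] for d in TEXTURE_DESCRIPTOR_NAMES for ch in CHANNEL_NAMES
    }
    n_used = 0
    for rec in records:
        if rec.patch is None or rec.patch_mask is None:
            raise ValueError(f"nucleus {rec.label} lacks an intensity patch")
        if rec.patch_mask.sum() < MIN_INTERIOR_PIXELS:
            log.info("skipping nucleus %d: fewer than %d interior pixels", rec.label, MIN_INTERIOR_PIXELS)
            continue
        ok = True
        values = {}
        for c, ch in enumerate(CHANNEL_NAMES):
            P = masked_glcm(rec.patch[..., c], rec.patch_mask)
            if P.sum() == 0:
                ok = False
                break
            values[ch] = glcm_descriptors(P)
            values[ch]["invariant_moment"] = _patch_invariant_moment(rec.patch[..., c], rec.patch_mask)
        if not ok:
            log.info("skipping nucleus %d: no interior co-occurrence pairs", rec.label)
            continue
        n_used += 1
        for ch in CHANNEL_NAMES:
            for d in TEXTURE_DESCRIPTOR_NAMES:
                per_channel[(d, ch)].append(values[ch][d])
    if n_used < 2:
        raise ValueError("insufficient nuclei with valid texture (need >= 2)")
    out: dict[str, float] = {}
    for d in TEXTURE_DESCRIPTOR_NAMES:
        for ch in CHANNEL_NAMES:
            vals = np.array(per_channel[(d, ch)], float)
            out[f"texture:{d}:{ch}:mean"] = float(vals.mean())
            out[f"texture:{d}:{ch}:sd"] = float(vals.std(ddof=1))
    return out
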