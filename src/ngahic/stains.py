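"""H&E color deconvolution.

An RGB stained-tissue image is unmixed into per-stain optical-density
(absorbance) rasters via the Beer-Lambert transform followed by projection
onto a stain basis.  The default basis is the published H&E(+residual)
absorption matrix shipped with scikit-image; it can be overridden when a
slide deviates from standard staining.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb_from_hed

#: rows = absorption spectra of hematoxylin, eosin, residual (unit norm)
_raw = np.asarray(rgb_from_hed)
DEFAULT_STAIN_BASIS = _raw / np.linalg.norm(_raw, axis=1, keepdims=True)

_EPS = 1e-6


def color_deconvolve(
    pixels: np.ndarray,
    stain_basis: np.ndarray | None = None,
    background: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an RGB image into (hematoxylin, eosin, residual) densities.

    Parameters
    ----------
    pixels
        H x W x 3 raster, either uint8 in [0, 255] or float transmittances.
    stain_basis
        3 x 3 matrix whose rows are stain absorption vectors in RGB space.
    background
        Intensity of unstained background (I0 in Beer-Lambert). Defaults to
        255 for integer images, 1.0 for float images.

    Returns
    -------
    Three H x W non-negative stain-density rasters.  A pure-background pixel
    maps to exactly zero density in every channel.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    if not np.any(px > 0):
        raise ValueError("all-zero image: optical density is undefined")
    if background is None:
        background = 255.0 if np.asarray(pixels).dtype.kind in "ui" else 1.0
    basis = DEFAULT_STAIN_BASIS if stain_basis is None else np.asarray(stain_basis, float)
    if basis.shape != (3, 3):
        raise ValueError("stain basis must be 3 x 3")
    norms = np.linalg.norm(basis, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain basis rows must be non-zero")
    basis = basis / norms

    transmittance = np.clip(px / background, _EPS, 1.0)
    od = -np.log10(transmittance)  # H x W x 3 absorbances
    density = od.reshape(-1, 3) @ np.linalg.inv(basis)
    density = np.clip(density, 0.0, None).reshape(px.shape)
    return density[..., 0], density[..., 1], density[..., 2]
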