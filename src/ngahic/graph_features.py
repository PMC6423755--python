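"""Tissue-architecture and orientation-disorder features.

Three families built on the nuclear centroid point pattern:

* Voronoi diagram (12 features): per-cell perimeter, mean chord and area,
  each aggregated by {average, SD, min/max ratio, disorder};
* Delaunay triangulation (8 features): edge lengths and triangle areas,
  each aggregated by {mean, SD, min/max ratio, disorder};
* cell-orientation co-occurrence (39 features): per-nucleus co-occurrence of
  quantized major-axis angles over k-nearest-neighbor neighborhoods, reduced
  to 13 Haralick-family descriptors and aggregated by {mean, SD, range}.

The disorder statistic is the bounded coefficient-of-variation transform
``1 - 1/(1 + SD/mean)``, which is 0 exactly when all values are equal and
approaches 1 as the relative spread diverges.
"""

from __future__ import annotations

import logging

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree

from .core import NucleusRecord

log = logging.getLogger(__name__)

ORIENTATION_BINS = 18  # 10 degrees each over [0, 180)
K_NEIGHBORS = 5

VORONOI_ATTRS = ("perimeter", "chord", "area")
VORONOI_STATS = ("average", "sd", "minmax_ratio", "disorder")
DELAUNAY_ATTRS = ("side_length", "triangle_area")
DELAUNAY_STATS = ("mean", "sd", "minmax_ratio", "disorder")
ORIENTATION_DESCRIPTOR_NAMES = (
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_average",
    "contrast_variance",
    "contrast_entropy",
    "intensity_average",
    "intensity_variance",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure_1",
    "info_measure_2",
)
ORIENTATION_STATS = ("mean", "sd", "range")


def disorder(values: np.ndarray) -> float:
    """``1 - 1/(1 + SD/mean)``; 0 iff SD = 0, always < 1."""
    values = np.asarray(values, float)
    mean = values.mean()
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0.0:
        return 0.0
    if mean == 0.0:  # CV diverges; cap just under the open upper bound
        return 1.0 - np.finfo(float).eps
    return float(1.0 - 1.0 / (1.0 + sd / abs(mean)))


def _minmax_ratio(values: np.ndarray) -> float:
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return 1.0
    return vmin / vmax if vmax != 0 else 0.0


def _aggregate(values: np.ndarray, stats: tuple[str, ...]) -> dict[str, float]:
    funcs = {
        "average": lambda v: float(v.mean()),
        "mean": lambda v: float(v.mean()),
        "sd": lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "minmax_ratio": _minmax_ratio,
        "disorder": disorder,
    }
    return {s: funcs[s](values) for s in stats}


# ---------------------------------------------------------------------------
# Voronoi


def _mean_chord(cell: shapely.Polygon) -> float:
    """Mean vertex-to-vertex diagonal through the cell centroid: for each
    vertex, the length of the full chord obtained by extending the
    vertex-to-centroid ray to the opposite boundary."""
    verts = np.asarray(cell.exterior.coords)[:-1]
    c = np.array([cell.centroid.x, cell.centroid.y])
    diam = 4.0 * max(cell.bounds[2] - cell.bounds[0], cell.bounds[3] - cell.bounds[1])
    chords = []
    for v in verts:
        d = c - v
        norm = np.linalg.norm(d)
        if norm == 0:
            continue
        far = c + d / norm * diam
        seg = shapely.LineString([v, far]).intersection(cell)
        chords.append(seg.length)
    return float(np.mean(chords)) if chords else 0.0


def voronoi_cells(centroids: np.ndarray, bbox: tuple[float, float, float, float]) -> list[shapely.Polygon]:
    """Voronoi tessellation of the centroids clipped to the bounding box
    ``(xmin, ymin, xmax, ymax)``; one polygon per cell (boundary cells are
    clipped, not discarded)."""
    pts = np.asarray(centroids, float)
    if len(pts) < 4:
        raise ValueError("need >= 4 centroids for Voronoi features")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("collinear centroids: tessellation has no bounded structure")
    box = shapely.box(*bbox)
    mp = shapely.MultiPoint(pts)
    try:
        raw = shapely.voronoi_polygons(mp, extend_to=box)
    except shapely.errors.GEOSException as exc:  # pragma: no cover
        raise ValueError(f"Voronoi tessellation failed: {exc}") from exc
    cells = [g.intersection(box) for g in raw.geoms]
    cells = [c for c in cells if not c.is_empty and c.area > 0]
    if len(cells) < 4:
        raise ValueError("degenerate tessellation (collinear centroids?)")
    return cells


def voronoi_features(
    centroids: np.ndarray, bbox: tuple[float, float, float, float] | None = None
) -> dict[str, float]:
    """The 12 Voronoi features ``voronoi:<attr>:<stat>``."""
    pts = np.asarray(centroids, float)
    if bbox is None:
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        bbox = (xmin, ymin, xmax, ymax)
    cells = voronoi_cells(pts, bbox)
    attrs = {
        "perimeter": np.array([c.exterior.length for c in cells]),
        "chord": np.array([_mean_chord(c) for c in cells]),
        "area": np.array([c.area for c in cells]),
    }
    out: dict[str, float] = {}
    for attr in VORONOI_ATTRS:
        agg = _aggregate(attrs[attr], VORONOI_STATS)
        for stat in VORONOI_STATS:
            out[f"voronoi:{attr}:{stat}"] = agg[stat]
    return out


# ---------------------------------------------------------------------------
# Delaunay


def delaunay_edges_triangles(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique edge lengths and triangle areas of the Delaunay triangulation."""
    pts = np.asarray(centroids, float)
    if len(pts) < 3:
        raise ValueError("need >= 3 centroids for Delaunay features")
    try:
        tri = Delaunay(pts)
    except Exception as exc:
        raise ValueError(f"Delaunay triangulation failed: {exc}") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate triangulation (collinear centroids?)")
    edges = set()
    areas = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        u, v = b - a, c - a
        areas.append(0.5 * abs(u[0] * v[1] - u[1] * v[0]))
        for i in range(3):
            edges.add(tuple(sorted((simplex[i], simplex[(i + 1) % 3]))))
    lengths = np.array([np.linalg.norm(pts[i] - pts[j]) for i, j in sorted(edges)])
    return lengths, np.array(areas)


def delaunay_features(centroids: np.ndarray) -> dict[str, float]:
    """The 8 Delaunay features ``delaunay:<attr>:<stat>``."""
    lengths, areas = delaunay_edges_triangles(centroids)
    out: dict[str, float] = {}
    for attr, values in (("side_length", lengths), ("triangle_area", areas)):
        agg = _aggregate(values, DELAUNAY_STATS)
        for stat in DELAUNAY_STATS:
            out[f"delaunay:{attr}:{stat}"] = agg[stat]
    return out


# ---------------------------------------------------------------------------
# orientation co-occurrence


def _cooc_descriptors(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick-family descriptors of one normalized orientation
    co-occurrence matrix."""
    B = P.shape[0]
    i, j = np.meshgrid(np.arange(B), np.arange(B), indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    diff = np.abs(i - j)
    summ = i + j

    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=B)
    p_sum = np.bincount(summ.ravel(), weights=P.ravel(), minlength=2 * B - 1)

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if len(p) else 0.0

    k_diff = np.arange(B)
    k_sum = np.arange(2 * B - 1)
    contrast_avg = float((k_diff * p_diff).sum())
    contrast_var = float(((k_diff - contrast_avg) ** 2 * p_diff).sum())
    intensity_avg = float((k_sum * p_sum).sum())
    intensity_var = float(((k_sum - intensity_avg) ** 2 * p_sum).sum())

    mu_x = float((np.arange(B) * px).sum())
    mu_y = float((np.arange(B) * py).sum())
    sd_x = float(np.sqrt(((np.arange(B) - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((np.arange(B) - mu_y) ** 2 * py).sum()))
    if sd_x > 0 and sd_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0

    hxy = ent(P.ravel())
    hx, hy = ent(px), ent(py)
    outer = np.outer(px, py)
    mask = (P > 0) & (outer > 0)
    hxy1 = float(-(P[mask] * np.log2(outer[mask])).sum()) if mask.any() else 0.0
    mask2 = outer > 0
    hxy2 = float(-(outer[mask2] * np.log2(outer[mask2])).sum()) if mask2.any() else 0.0
    denom = max(hx, hy)
    info1 = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    info2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    return {
        "contrast_energy": float((P * diff**2).sum()),
        "contrast_inverse_moment": float((P / (1.0 + diff**2)).sum()),
        "contrast_average": contrast_avg,
        "contrast_variance": contrast_var,
        "contrast_entropy": ent(p_diff),
        "intensity_average": intensity_avg,
        "intensity_variance": intensity_var,
        "intensity_entropy": ent(p_sum),
        "entropy": hxy,
        "energy": float((P**2).sum()),
        "correlation": correlation,
        "info_measure_1": info1,
        "info_measure_2": info2,
    }


def orientation_cooccurrence(
    angles: np.ndarray,
    positions: np.ndarray,
    k_neighbors: int = K_NEIGHBORS,
    n_bins: int = ORIENTATION_BINS,
) -> list[np.ndarray]:
    """One symmetric normalized B x B co-occurrence matrix per nucleus, of
    (own orientation bin, neighbor orientation bin) over its k nearest
    neighbors."""
    angles = np.asarray(angles, float)
    positions = np.asarray(positions, float)
    n = len(angles)
    if n < k_neighbors + 1:
        raise ValueError(f"need >= {k_neighbors + 1} nuclei with defined orientation")
    bins = np.minimum((angles % 180.0) / 180.0 * n_bins, n_bins - 1).astype(int)
    tree = cKDTree(positions)
    _, idx = tree.query(positions, k=k_neighbors + 1)
    matrices = []
    for i in range(n):
        C = np.zeros((n_bins, n_bins))
        for j in idx[i, 1:]:
            C[bins[i], bins[j]] += 1.0
        C = C + C.T
        matrices.append(C / C.sum())
    return matrices


def orientation_features(
    records: list[NucleusRecord],
    k_neighbors: int = K_NEIGHBORS,
    n_bins: int = ORIENTATION_BINS,
) -> dict[str, float]:
    """The 39 orientation-disorder features ``orient:<descriptor>:<stat>``.

    Nuclei with undefined orientation (near-circular) are excluded; if they
    are the majority a warning is logged and the defined subset is used.
    """
    defined = [r for r in records if r.orientation_defined]
    if len(records) and len(defined) < 0.5 * len(records):
        log.warning(
            "only %d/%d nuclei have defined orientation; computing on the defined subset",
            len(defined),
            len(records),
        )
    angles = np.array([r.orientation for r in defined])
    positions = np.array([r.centroid for r in defined])
    matrices = orientation_cooccurrence(angles, positions, k_neighbors, n_bins)
    per_desc = {name: [] for name in ORIENTATION_DESCRIPTOR_NAMES}
    for P in matrices:
        desc = _cooc_descriptors(P)
        for name in ORIENTATION_DESCRIPTOR_NAMES:
            per_desc[name].append(desc[name])
    out: dict[str, float] = {}
    for name in ORIENTATION_DESCRIPTOR_NAMES:
        vals = np.array(per_desc[name], float)
        out[f"orient:{name}:mean"] = float(vals.mean())
        out[f"orient:{name}:sd"] = float(vals.std(ddof=1))
        out[f"orient:{name}:range"] = float(vals.max() - vals.min())
    return out
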