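"""Architecture (Voronoi/Delaunay) and orientation co-occurrence features:
hand-enumerated fixtures, an independent geometry oracle, and invariances."""

import numpy as np
import pytest
import shapely
from scipy.spatial import Voronoi

from ngahic.core import NucleusRecord
from ngahic.features import assemble_feature_vector, family_names
from ngahic.graph_features import (
    delaunay_edges_triangles,
    delaunay_features,
    disorder,
    orientation_cooccurrence,
    orientation_features,
    voronoi_cells,
    voronoi_features,
)


def oriented_record(label, x, y, angle, defined=True):
    return NucleusRecord(
        label=label, centroid=(float(x), float(y)), boundary=np.zeros((8, 2)),
        area=10.0, perimeter=10.0, orientation=float(angle), eccentricity=0.7,
        orientation_defined=defined,
    )


class TestDisorder:
    def test_bounds_and_zero_iff_constant(self, rng):
        for _ in range(50):
            v = rng.gamma(2.0, 1.0, size=rng.integers(2, 30))
            d = disorder(v)
            assert 0.0 <= d < 1.0
            assert (d == 0.0) == (v.std(ddof=1) == 0.0)
        assert disorder(np.array([3.0, 3.0, 3.0])) == 0.0


class TestVoronoi:
    def test_regular_grid_interior_congruent(self):
        """Grid centers tiling the box exactly: every clipped cell is a unit
        square, so SD = 0, disorder = 0, min/max = 1."""
        pts = np.array([[i + 0.5, j + 0.5] for i in range(5) for j in range(5)], float)
        feats = voronoi_features(pts, bbox=(0.0, 0.0, 5.0, 5.0))
        assert len(feats) == 12
        for attr in ("perimeter", "chord", "area"):
            assert feats[f"voronoi:{attr}:sd"] == pytest.approx(0.0, abs=1e-9)
            assert feats[f"voronoi:{attr}:disorder"] == pytest.approx(0.0, abs=1e-9)
            assert feats[f"voronoi:{attr}:minmax_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert feats["voronoi:area:average"] == pytest.approx(1.0, abs=1e-9)

    def test_against_scipy_oracle(self, rng):
        """Cell areas/perimeters match an independent scipy.spatial.Voronoi
        computation for every finite cell lying strictly inside the box."""
        pts = rng.uniform(0, 100, size=(20, 2))
        bbox = (0.0, 0.0, 100.0, 100.0)
        cells = voronoi_cells(pts, bbox)
        vor = Voronoi(pts)
        box = shapely.box(*bbox)
        checked = 0
        for i, region_idx in enumerate(vor.point_region):
            region = vor.regions[region_idx]
            if -1 in region or len(region) == 0:
                continue
            oracle_poly = shapely.Polygon(vor.vertices[region])
            if not oracle_poly.within(box):
                continue
            mine = [c for c in cells if c.contains(shapely.Point(pts[i]))]
            assert len(mine) == 1
            assert mine[0].area == pytest.approx(oracle_poly.area, abs=1e-6)
            assert mine[0].exterior.length == pytest.approx(oracle_poly.exterior.length, abs=1e-6)
            checked += 1
        assert checked >= 5

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        with pytest.raises(ValueError):
            voronoi_features(pts, bbox=(0, 0, 10, 10))

    def test_rigid_motion_invariance(self):
        """A 90-degree rotation about the box center leaves all 12 aggregates
        unchanged (the square clipping box maps onto itself)."""
        rng = np.random.default_rng(7)
        pts = rng.uniform(10, 90, size=(25, 2))
        bbox = (0.0, 0.0, 100.0, 100.0)
        f1 = voronoi_features(pts, bbox=bbox)
        center = np.array([50.0, 50.0])
        rotated = np.column_stack([
            center[0] - (pts[:, 1] - center[1]),
            center[1] + (pts[:, 0] - center[0]),
        ])
        f2 = voronoi_features(rotated, bbox=bbox)
        for k in f1:
            assert f2[k] == pytest.approx(f1[k], abs=1e-6)


class TestDelaunay:
    def test_equilateral_triangle(self):
        pts = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]], float)
        feats = delaunay_features(pts)
        assert len(feats) == 8
        assert feats["delaunay:side_length:mean"] == pytest.approx(1.0)
        assert feats["delaunay:side_length:sd"] == pytest.approx(0.0, abs=1e-12)
        assert feats["delaunay:side_length:disorder"] == pytest.approx(0.0, abs=1e-9)
        assert feats["delaunay:triangle_area:mean"] == pytest.approx(np.sqrt(3) / 4)

    def test_unit_square_hand_enumeration(self):
        """Four corners of a unit square triangulate into two triangles with
        edge multiset {1, 1, 1, 1, sqrt(2)}."""
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        lengths, areas = delaunay_edges_triangles(pts)
        assert sorted(np.round(lengths, 12)) == pytest.approx([1, 1, 1, 1, np.sqrt(2)])
        assert list(np.round(sorted(areas), 12)) == pytest.approx([0.5, 0.5])
        feats = delaunay_features(pts)
        expected = np.array([1, 1, 1, 1, np.sqrt(2)])
        assert feats["delaunay:side_length:mean"] == pytest.approx(expected.mean())
        assert feats["delaunay:side_length:sd"] == pytest.approx(expected.std(ddof=1))
        assert feats["delaunay:side_length:minmax_ratio"] == pytest.approx(1 / np.sqrt(2))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            delaunay_features(np.array([[0, 0], [1, 1]], float))

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(0, 50, size=(30, 2))
        th = np.deg2rad(33.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        f1 = delaunay_features(pts)
        f2 = delaunay_features(pts @ rot.T + np.array([7.0, -3.0]))
        for k in f1:
            assert f2[k] == pytest.approx(f1[k], abs=1e-6)


class TestOrientation:
    def test_hand_built_five_nucleus_example(self):
        """Five collinear nuclei, four 45-degree bins, k = 2: every
        per-nucleus co-occurrence matrix and the descriptors of the last one
        are enumerated by hand."""
        angles = np.array([10.0, 15.0, 100.0, 105.0, 170.0])
        positions = np.column_stack([np.arange(5.0), np.zeros(5)])
        mats = orientation_cooccurrence(angles, positions, k_neighbors=2, n_bins=4)

        def m(entries):
            M = np.zeros((4, 4))
            for (i, j), v in entries.items():
                M[i, j] = v
            return M

        expected = [
            m({(0, 0): 0.5, (0, 2): 0.25, (2, 0): 0.25}),
            m({(0, 0): 0.5, (0, 2): 0.25, (2, 0): 0.25}),
            m({(2, 2): 0.5, (0, 2): 0.25, (2, 0): 0.25}),
            m({(2, 2): 0.5, (2, 3): 0.25, (3, 2): 0.25}),
            m({(2, 3): 0.5, (3, 2): 0.5}),
        ]
        for got, exp in zip(mats, expected):
            np.testing.assert_allclose(got, exp, atol=1e-12)

        # descriptors of the last matrix, by hand
        from ngahic.graph_features import _cooc_descriptors

        d = _cooc_descriptors(expected[4])
        assert d["entropy"] == pytest.approx(1.0, abs=1e-9)
        assert d["energy"] == pytest.approx(0.5, abs=1e-9)
        assert d["contrast_energy"] == pytest.approx(1.0, abs=1e-9)
        assert d["contrast_inverse_moment"] == pytest.approx(0.5, abs=1e-9)
        assert d["contrast_average"] == pytest.approx(1.0, abs=1e-9)
        assert d["contrast_variance"] == pytest.approx(0.0, abs=1e-9)
        assert d["contrast_entropy"] == pytest.approx(0.0, abs=1e-9)
        assert d["intensity_average"] == pytest.approx(5.0, abs=1e-9)
        assert d["intensity_variance"] == pytest.approx(0.0, abs=1e-9)
        assert d["intensity_entropy"] == pytest.approx(0.0, abs=1e-9)
        assert d["correlation"] == pytest.approx(-1.0, abs=1e-9)
        assert d["info_measure_1"] == pytest.approx(-1.0, abs=1e-9)
        assert d["info_measure_2"] == pytest.approx(np.sqrt(1 - np.exp(-2.0)), abs=1e-9)

    def test_aligned_nuclei_zero_entropy(self, rng):
        records = [
            oriented_record(i, x, y, 37.0)
            for i, (x, y) in enumerate(rng.uniform(0, 100, size=(12, 2)))
        ]
        feats = orientation_features(records, k_neighbors=3)
        assert len(feats) == 39
        assert feats["orient:entropy:mean"] == 0.0
        assert feats["orient:entropy:sd"] == 0.0
        assert feats["orient:entropy:range"] == 0.0
        assert feats["orient:energy:mean"] == 1.0

    def test_undefined_orientations_excluded(self, rng):
        records = [
            oriented_record(i, x, y, 37.0)
            for i, (x, y) in enumerate(rng.uniform(0, 100, size=(10, 2)))
        ]
        records += [oriented_record(99, 5, 5, 0.0, defined=False)]
        feats = orientation_features(records, k_neighbors=3)
        assert feats["orient:entropy:mean"] == 0.0  # circular nucleus ignored

    def test_too_few_defined_rejected(self):
        records = [oriented_record(i, i, 0.0, 10.0) for i in range(3)]
        with pytest.raises(ValueError, match="defined orientation"):
            orientation_features(records, k_neighbors=5)


class TestAssembly:
    def _families(self, fill=0.5):
        return {
            fam: {name: fill for name in family_names(fam)}
            for fam in ("shape", "texture", "orientation", "voronoi", "delaunay")
        }

    def test_valid_assembly(self):
        fams = self._families()
        fv = assemble_feature_vector(
            fams["shape"], fams["texture"], fams["orientation"],
            fams["voronoi"], fams["delaunay"], spot_id="s1",
        )
        assert len(fv) == 189
        assert fv.values.index.is_unique

    def test_wrong_family_length_named_in_error(self):
        fams = self._families()
        bad = dict(fams["shape"])
        bad.pop(next(iter(bad)))
        with pytest.raises(ValueError, match="family shape expected 100"):
            assemble_feature_vector(bad, fams["texture"], fams["orientation"],
                                    fams["voronoi"], fams["delaunay"])

    def test_assembly_deterministic(self):
        fams = self._families(0.25)
        args = (fams["shape"], fams["texture"], fams["orientation"],
                fams["voronoi"], fams["delaunay"])
        v1 = assemble_feature_vector(*args).values
        v2 = assemble_feature_vector(*args).values
        assert (v1 == v2).all()
        assert list(v1.index) == list(v2.index)
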