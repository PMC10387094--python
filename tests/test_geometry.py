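"""Range loading/filtering, the equal-area projection, and overlap areas."""

import json
import math

import numpy as np
import pytest
from shapely.geometry import box, mapping

from cladedensity import (
    FilterSpec,
    OverlapMatrix,
    RangePolygonSet,
    compute_overlap_matrix,
    load_ranges,
    project_equal_area,
    summarize_distributions,
)
from cladedensity.geometry import (
    AUTHALIC_RADIUS_KM,
    CRS_CEA_KM,
    CRS_GEOGRAPHIC,
    GeometryError,
)
from cladedensity.synthetic import ScenarioConfig, simulate_clade

R = AUTHALIC_RADIUS_KM


def _write_geojson(path, features):
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc))


def _feature(geom, species, presence="extant", origin="native"):
    return {
        "type": "Feature",
        "properties": {
            "species_id": species,
            "presence": presence,
            "origin": origin,
        },
        "geometry": mapping(geom),
    }


class TestLoadRanges:
    def test_introduced_feature_dropped_before_dissolve(self, tmp_path):
        path = tmp_path / "r.geojson"
        _write_geojson(
            path,
            [
                _feature(box(0, 0, 1, 1), "sp1"),
                _feature(box(2, 0, 3, 1), "sp1"),
                _feature(box(10, 10, 11, 11), "sp1", origin="introduced"),
            ],
        )
        ranges = load_ranges(path, crs=CRS_CEA_KM)
        assert ranges.geoms["sp1"].area == pytest.approx(2.0)
        assert ranges.report.n_features_dropped == 1

    def test_species_with_all_features_excluded_is_reported(self, tmp_path):
        path = tmp_path / "r.geojson"
        _write_geojson(
            path,
            [
                _feature(box(0, 0, 1, 1), "keep"),
                _feature(box(0, 0, 1, 1), "gone", presence="uncertain"),
            ],
        )
        ranges = load_ranges(path, crs=CRS_CEA_KM)
        assert "gone" not in ranges.geoms
        assert ranges.report.species_all_excluded == ["gone"]

    def test_missing_filter_field_is_an_error(self, tmp_path):
        path = tmp_path / "r.geojson"
        _write_geojson(
            path,
            [
                {
                    "type": "Feature",
                    "properties": {"species_id": "sp1"},
                    "geometry": mapping(box(0, 0, 1, 1)),
                }
            ],
        )
        with pytest.raises(GeometryError, match="presence"):
            load_ranges(path)
        assert len(load_ranges(path, filter_spec=None, crs=CRS_CEA_KM)) == 1

    def test_bowtie_polygon_repaired_with_correct_area(self, tmp_path):
        # self-intersecting ring (0,0)->(2,2)->(2,0)->(0,2): two triangles
        # of area 1 each around the crossing point (1,1)
        path = tmp_path / "r.geojson"
        _write_geojson(
            path,
            [
                {
                    "type": "Feature",
                    "properties": {
                        "species_id": "bow",
                        "presence": "extant",
                        "origin": "native",
                    },
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[0, 0], [2, 2], [2, 0], [0, 2], [0, 0]]
                        ],
                    },
                }
            ],
        )
        ranges = load_ranges(path, crs=CRS_CEA_KM)
        assert ranges.geoms["bow"].is_valid
        assert ranges.geoms["bow"].area == pytest.approx(2.0)
        assert ranges.report.n_features_repaired == 1

    def test_unreadable_file(self, tmp_path):
        with pytest.raises(GeometryError):
            load_ranges(tmp_path / "nope.geojson")


class TestProjection:
    def _project_one(self, geom):
        rs = RangePolygonSet({"x": geom}, crs=CRS_GEOGRAPHIC)
        return project_equal_area(rs).geoms["x"]

    def test_full_sphere_area(self):
        area = self._project_one(box(-180, -90, 180, 90)).area
        assert area == pytest.approx(4 * math.pi * R * R, rel=1e-3)

    def test_spherical_zone_closed_form(self):
        """Band 0..30N over all longitudes: 2 pi R^2 sin(30) = pi R^2."""
        area = self._project_one(box(-180, 0, 180, 30)).area
        assert area == pytest.approx(math.pi * R * R, rel=1e-3)

    def test_congruent_cells_shrink_with_latitude(self):
        """Two 10x10 degree cells at 0 and 60 latitude have the spherical
        area ratio (sin10-sin0)/(sin70-sin60), not 1:1."""
        low = self._project_one(box(0, 0, 10, 10)).area
        high = self._project_one(box(0, 60, 10, 70)).area
        expected = (math.sin(math.radians(10)) - 0.0) / (
            math.sin(math.radians(70)) - math.sin(math.radians(60))
        )
        assert low / high == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_spherical_cap_oracle(self, seed):
        """Random polar caps: projected area matches 2 pi R^2 (1 - cos t)
        within 0.1%."""
        rng = np.random.default_rng(seed)
        theta = math.degrees(rng.uniform(0.1, 1.2))
        cap = box(-180, 90 - theta, 180, 90)
        area = self._project_one(cap).area
        expected = 2 * math.pi * R * R * (1 - math.cos(math.radians(theta)))
        assert area == pytest.approx(expected, rel=1e-3)

    def test_out_of_bounds_coordinates_rejected(self):
        rs = RangePolygonSet({"x": box(100, 80, 200, 95)}, crs=CRS_GEOGRAPHIC)
        with pytest.raises(GeometryError, match="longitude|latitude"):
            project_equal_area(rs)

    def test_rejects_already_projected_input(self):
        rs = RangePolygonSet({"x": box(0, 0, 1, 1)}, crs=CRS_CEA_KM)
        with pytest.raises(GeometryError, match="expects"):
            project_equal_area(rs)


def _overlap_oracle(ranges: RangePolygonSet) -> np.ndarray:
    """Exhaustive double loop without the bounding-box prefilter."""
    geoms = [ranges.geoms[s] for s in ranges.species]
    n = len(geoms)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                m[i, i] = geoms[i].area
            else:
                m[i, j] = geoms[i].intersection(geoms[j]).area
    return m


class TestOverlapMatrix:
    def _set(self, geoms):
        return RangePolygonSet(geoms, crs=CRS_CEA_KM)

    def test_identical_unit_squares(self):
        om = compute_overlap_matrix(
            self._set({"a": box(0, 0, 1, 1), "b": box(0, 0, 1, 1)})
        )
        assert om.matrix[0, 1] == pytest.approx(1.0)

    def test_disjoint_squares(self):
        om = compute_overlap_matrix(
            self._set({"a": box(0, 0, 1, 1), "b": box(5, 5, 6, 6)})
        )
        assert om.matrix[0, 1] == 0.0

    def test_half_offset_squares(self):
        om = compute_overlap_matrix(
            self._set({"a": box(0, 0, 1, 1), "b": box(0.5, 0, 1.5, 1)})
        )
        assert om.matrix[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_pair_bound_on_synthetic_clade(self):
        clade = simulate_clade(ScenarioConfig(n_tips=40, seed=9))
        om = compute_overlap_matrix(clade.ranges)
        m = om.matrix
        assert np.allclose(m, m.T)
        cap = np.minimum.outer(m.diagonal(), m.diagonal())
        assert np.all(m <= cap + 1e-6 * m.max())

    def test_coordinate_scaling_scales_areas_quadratically(self):
        clade = simulate_clade(ScenarioConfig(n_tips=12, seed=10))
        om = compute_overlap_matrix(clade.ranges)
        import shapely

        scaled = RangePolygonSet(
            {
                sp: shapely.transform(g, lambda c: 3.0 * c)
                for sp, g in clade.ranges.geoms.items()
            },
            crs=CRS_CEA_KM,
        )
        om_scaled = compute_overlap_matrix(scaled)
        assert np.allclose(om_scaled.matrix, 9.0 * om.matrix, rtol=1e-9)

    @pytest.mark.parametrize("seed", [13, 14])
    def test_bbox_prefilter_matches_exhaustive_loop(self, seed):
        clade = simulate_clade(ScenarioConfig(n_tips=30, seed=seed))
        om = compute_overlap_matrix(clade.ranges)
        assert np.array_equal(om.matrix, _overlap_oracle(clade.ranges))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(GeometryError, match="exceeds"):
            OverlapMatrix(("a", "b"), np.array([[1.0, 5.0], [5.0, 1.0]]))

    def test_tsv_round_trip(self, tmp_path):
        clade = simulate_clade(ScenarioConfig(n_tips=8, seed=15))
        om = compute_overlap_matrix(clade.ranges)
        path = tmp_path / "o.tsv"
        om.to_tsv(path)
        back = OverlapMatrix.from_tsv(path)
        assert back.species == om.species
        assert np.allclose(back.matrix, om.matrix)


class TestSummarizeDistributions:
    def test_log_mean_closed_form(self):
        s = summarize_distributions(
            [math.e, math.e**2, math.e**3], [0.0, 0.0, 4.0]
        )
        assert s.range_log_mean == pytest.approx(2.0)
        assert s.overlap_log_mean == pytest.approx(math.log(4.0))
        assert s.n_positive_overlaps == 1

    def test_all_zero_overlaps_flagged_not_fatal(self):
        s = summarize_distributions([1.0, 2.0], [0.0, 0.0])
        assert s.overlap_empty
        assert s.overlap_log_mean is None

    def test_overlap_log_mean_below_range_log_mean_on_synthetic_clade(self):
        """Intersections cannot exceed either operand, so the overlap
        distribution sits left of the range-size distribution."""
        clade = simulate_clade(ScenarioConfig(n_tips=60, seed=16))
        om = compute_overlap_matrix(clade.ranges)
        s = summarize_distributions(
            om.range_sizes().to_numpy(), om.pairwise_overlaps()
        )
        assert not s.overlap_empty
        assert s.overlap_log_mean <= s.range_log_mean
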