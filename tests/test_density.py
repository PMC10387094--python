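"""The clade-density statistic: alignment, row sums, deciles, summaries."""

import json

import numpy as np
import pytest

from cladedensity import (
    OverlapMatrix,
    VcvMatrix,
    align_species,
    clade_density,
    export_top_decile_geo,
    read_newick,
    summarize_density,
    top_decile,
    vcv,
)
from cladedensity.density import CladeDensityTable, DensityError
from cladedensity.geometry import CRS_CEA_KM, RangePolygonSet, load_ranges
from cladedensity.synthetic import ScenarioConfig, simulate_clade

from conftest import random_tree


def _random_instance(n, seed):
    """A valid random (overlap, vcv) pair on a simulated tree."""
    rng = np.random.default_rng(seed)
    tree = random_tree(n, seed=seed)
    V = vcv(tree)
    areas = rng.lognormal(2.0, 1.0, n)
    m = np.zeros((n, n))
    np.fill_diagonal(m, areas)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:  # sympatric pair
                m[i, j] = m[j, i] = rng.random() * min(areas[i], areas[j])
    return OverlapMatrix(V.species, m), V


def _brute_force_cd(O, C, include_self=False):
    n = O.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j and not include_self:
                continue
            out[i] += O[i, j] * C[i, j]
    return out


class TestAlignSpecies:
    def test_drops_are_reported_on_both_sides(self):
        O = OverlapMatrix(("B", "C", "D"), np.diag([1.0, 2.0, 3.0]))
        V = vcv(read_newick("((A:1,B:1):1,C:2);"))
        o, v, rep = align_species(O, V)
        assert o.species == v.species == ("B", "C")
        assert rep.dropped_no_geography == ("A",)
        assert rep.dropped_no_tree == ("D",)

    def test_identical_sets_identity(self):
        O, V = _random_instance(6, seed=1)
        o, v, rep = align_species(O, V)
        assert o.species == O.species
        assert rep.dropped_no_geography == () and rep.dropped_no_tree == ()

    def test_empty_intersection_is_an_error(self):
        O = OverlapMatrix(("X", "Y"), np.diag([1.0, 1.0]))
        V = vcv(read_newick("(A:1,B:1);"))
        with pytest.raises(DensityError, match="no species shared"):
            align_species(O, V)

    def test_input_order_does_not_change_density(self):
        O, V = _random_instance(10, seed=2)
        base = clade_density(O, V).series()
        perm = np.random.default_rng(3).permutation(10)
        sp = tuple(O.species[i] for i in perm)
        O2 = OverlapMatrix(sp, O.matrix[np.ix_(perm, perm)])
        o2, v2, _ = align_species(O2, V)
        shuffled = clade_density(o2, v2).series()
        assert np.allclose(base.sort_index(), shuffled.sort_index())


class TestCladeDensity:
    def test_allopatric_clade_has_zero_density(self):
        n = 8
        tree = random_tree(n, seed=5)
        V = vcv(tree)
        O = OverlapMatrix(V.species, np.diag(np.full(n, 7.0)))
        assert np.all(clade_density(O, V).values == 0.0)

    def test_single_sympatric_pair_closed_form(self, three_tip_tree):
        V = vcv(three_tip_tree)
        m = np.diag([5.0, 5.0, 5.0])
        m[0, 1] = m[1, 0] = 2.0
        cd = clade_density(OverlapMatrix(V.species, m), V).series()
        assert cd["A"] == pytest.approx(1.0)  # 2.0 overlap x 0.5 shared time
        assert cd["B"] == pytest.approx(1.0)
        assert cd["C"] == 0.0

    @pytest.mark.parametrize("include_self", [False, True])
    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_matches_brute_force_double_loop(self, seed, include_self):
        O, V = _random_instance(8, seed=seed)
        got = clade_density(O, V, include_self=include_self).values
        want = _brute_force_cd(O.matrix, V.matrix, include_self)
        assert np.allclose(got, want, rtol=1e-9)

    def test_bilinearity_in_overlap_and_weights(self):
        O, V = _random_instance(9, seed=9)
        base = clade_density(O, V).values
        O2 = OverlapMatrix(O.species, 2.5 * O.matrix)
        V3 = VcvMatrix(V.species, 3.0 * V.matrix)
        assert np.allclose(clade_density(O2, V).values, 2.5 * base)
        assert np.allclose(clade_density(O, V3).values, 3.0 * base)
        assert np.allclose(
            clade_density(O, V, area_scale=10.0).values, base / 10.0
        )

    def test_monotone_in_single_overlap_entry(self):
        O, V = _random_instance(7, seed=10)
        base = clade_density(O, V).values
        m = O.matrix.copy()
        i, j = 0, 3
        bump = 0.5 * (min(m[i, i], m[j, j]) - m[i, j])
        m[i, j] += bump
        m[j, i] += bump
        bumped = clade_density(OverlapMatrix(O.species, m), V).values
        assert bumped[i] >= base[i] and bumped[j] >= base[j]
        others = [k for k in range(7) if k not in (i, j)]
        assert np.allclose(bumped[others], base[others])

    def test_misaligned_orders_rejected(self):
        O, V = _random_instance(5, seed=11)
        V2 = VcvMatrix(tuple(reversed(V.species)), V.matrix[::-1, ::-1])
        with pytest.raises(DensityError, match="align_species"):
            clade_density(O, V2)

    def test_inverse_patristic_weight_mode(self, three_tip_tree):
        V = vcv(three_tip_tree)
        m = np.diag([5.0, 5.0, 5.0])
        m[0, 1] = m[1, 0] = 2.0
        cd = clade_density(OverlapMatrix(V.species, m), V, weight="inv-patristic")
        # d(A,B) = 1.0, so weight 1/1 = 1 and CD_A = 2.0
        assert cd.series()["A"] == pytest.approx(2.0)


class TestTopDecile:
    def _table(self, values):
        sp = tuple(f"s{i}" for i in range(len(values)))
        return CladeDensityTable(sp, np.asarray(values, dtype=float))

    def test_ten_distinct_values_selects_single_maximum(self):
        sel = top_decile(self._table(np.arange(10.0)))
        assert sel.species == ("s9",)

    def test_ceil_rounding_at_25(self):
        sel = top_decile(self._table(np.arange(25.0)))
        assert len(sel.species) == 3  # ceil(2.5)

    def test_all_tied_returns_everything_with_warning(self):
        with pytest.warns(UserWarning, match="tied"):
            sel = top_decile(self._table(np.full(20, 4.0)))
        assert len(sel.species) == 20
        assert sel.n_ties_included == 18


class TestSummarizeDensity:
    def test_linear_interpolation_quartiles(self):
        sp = tuple("abcde")
        box = summarize_density(
            CladeDensityTable(sp, np.array([0.0, 1, 2, 3, 4]))
        )
        assert (box.q1, box.median, box.q3) == (1.0, 2.0, 3.0)
        assert box.lower_whisker == 0.0 and box.upper_whisker == 4.0

    def test_single_value_degenerate(self):
        box = summarize_density(CladeDensityTable(("a",), np.array([7.0])))
        assert (
            box.minimum
            == box.lower_whisker
            == box.median
            == box.upper_whisker
            == box.maximum
            == 7.0
        )

    def test_tukey_whisker_excludes_outlier(self):
        values = np.zeros(20)
        values[-1] = 100.0
        sp = tuple(f"s{i}" for i in range(20))
        box = summarize_density(CladeDensityTable(sp, values))
        assert box.upper_whisker == 0.0
        assert box.maximum == 100.0


class TestExportTopDecile:
    def _setup(self, tmp_path, n=10, seed=20):
        clade = simulate_clade(ScenarioConfig(n_tips=n, seed=seed))
        from cladedensity import compute_overlap_matrix

        om = compute_overlap_matrix(clade.ranges)
        o, v, rep = align_species(om, vcv(clade.tree))
        table = clade_density(o, v, alignment=rep)
        return clade.ranges, table

    def test_single_species_single_feature(self, tmp_path):
        ranges, table = self._setup(tmp_path)
        out = tmp_path / "top.geojson"
        export_top_decile_geo(ranges, [table.species[0]], table, out)
        doc = json.loads(out.read_text())
        assert len(doc["features"]) == 1
        assert doc["features"][0]["properties"]["species_id"] == table.species[0]

    def test_empty_selection_is_valid_empty_collection(self, tmp_path):
        ranges, table = self._setup(tmp_path)
        out = tmp_path / "empty.geojson"
        export_top_decile_geo(ranges, [], table, out)
        assert json.loads(out.read_text())["features"] == []

    def test_missing_geometry_is_an_error(self, tmp_path):
        ranges, table = self._setup(tmp_path)
        with pytest.raises(DensityError, match="ghost"):
            export_top_decile_geo(ranges, ["ghost"], table, tmp_path / "x.geojson")

    def test_round_trip_preserves_area(self, tmp_path):
        ranges, table = self._setup(tmp_path)
        sel = top_decile(table)
        out = tmp_path / "top.geojson"
        export_top_decile_geo(ranges, sel, table, out)
        back = load_ranges(out, filter_spec=None, crs=CRS_CEA_KM)
        for sp in sel.species:
            assert back.geoms[sp].area == pytest.approx(
                ranges.geoms[sp].area, rel=1e-9
            )
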