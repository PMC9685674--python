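"""Raw metric computations: EOO, region assignment, plasticity, domatia, interactions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladespec import metrics as m


# ---------------------------------------------------------------------------
# EOO


def _gc_dist(p1, p2):
    lam1, phi1, lam2, phi2 = map(math.radians, (p1[0], p1[1], p2[0], p2[1]))
    h = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * math.asin(math.sqrt(h))


def _spherical_triangle_excess(a, b, c):
    """l'Huilier's theorem; sides are great-circle angles."""
    s = (a + b + c) / 2
    t = math.tan(s / 2) * math.tan((s - a) / 2) * math.tan((s - b) / 2) * math.tan((s - c) / 2)
    return 4 * math.atan(math.sqrt(max(t, 0.0)))


def spherical_polygon_area_km2(vertices):
    """Independent spherical-excess area of a small convex polygon (fan triangulation)."""
    total = 0.0
    for i in range(1, len(vertices) - 1):
        p0, p1, p2 = vertices[0], vertices[i], vertices[i + 1]
        total += _spherical_triangle_excess(
            _gc_dist(p0, p1), _gc_dist(p1, p2), _gc_dist(p0, p2)
        )
    return total * m.EARTH_RADIUS_KM**2


class TestEoo:
    def test_duplicates_do_not_change_area(self):
        lon = [0.0, 0.3, 0.1]
        lat = [0.0, 0.1, 0.4]
        base = m.compute_eoo(lon, lat).area_km2
        dup = m.compute_eoo(lon * 3, lat * 3).area_km2
        assert dup == pytest.approx(base, rel=1e-12)

    def test_two_points_is_degenerate_missing(self):
        res = m.compute_eoo([0.0, 1.0], [0.0, 1.0])
        assert res.area_km2 is None and res.degenerate

    def test_collinear_points_degenerate(self):
        res = m.compute_eoo([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        assert res.area_km2 is None and res.degenerate

    def test_equatorial_square_matches_spherical_excess_oracle(self):
        verts = [(0.0, 0.0), (0.1, 0.0), (0.1, 0.1), (0.0, 0.1)]
        expect = spherical_polygon_area_km2(verts)
        got = m.compute_eoo([v[0] for v in verts], [v[1] for v in verts]).area_km2
        assert got == pytest.approx(expect, rel=0.005)

    def test_high_latitude_square_matches_oracle(self):
        # at 60N a degree of longitude is half as wide; equal-area projection must see that
        verts = [(10.0, 60.0), (10.5, 60.0), (10.5, 60.4), (10.0, 60.4)]
        expect = spherical_polygon_area_km2(verts)
        got = m.compute_eoo([v[0] for v in verts], [v[1] for v in verts]).area_km2
        assert got == pytest.approx(expect, rel=0.005)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_permutation_and_interior_point_invariance(self, seed):
        rng = np.random.default_rng(seed)
        lon = rng.uniform(-3, 3, 12)
        lat = rng.uniform(40, 44, 12)
        base = m.compute_eoo(lon, lat).area_km2
        perm = rng.permutation(12)
        assert m.compute_eoo(lon[perm], lat[perm]).area_km2 == pytest.approx(base, rel=1e-9)
        # a point at the centroid lies inside the hull: area unchanged
        lon2 = np.append(lon, lon.mean())
        lat2 = np.append(lat, lat.mean())
        assert m.compute_eoo(lon2, lat2).area_km2 == pytest.approx(base, rel=1e-6)
        # a far outside point can only grow the hull
        lon3 = np.append(lon, 10.0)
        lat3 = np.append(lat, 50.0)
        assert m.compute_eoo(lon3, lat3).area_km2 >= base


# ---------------------------------------------------------------------------
# Region assignment and DEL


def _ray_cast(point, ring):
    """Textbook even-odd ray casting, independent of shapely."""
    x, y = point
    inside = False
    for (x1, y1), (x2, y2) in zip(ring, ring[1:]):
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def _grid(nx=2, ny=2, size=1.0):
    feats = []
    for j in range(ny):
        for i in range(nx):
            x0, y0 = i * size, j * size
            ring = [(x0, y0), (x0 + size, y0), (x0 + size, y0 + size), (x0, y0 + size), (x0, y0)]
            feats.append((f"r{j}{i}", ring))
    return feats


def _regions_from_grid(feats):
    from shapely.geometry import Polygon

    return [f[0] for f in feats], [Polygon(f[1]) for f in feats]


class TestAssignRegions:
    def test_point_inside_square(self):
        ids, geoms = _regions_from_grid(_grid())
        occ = pd.DataFrame({"species": ["A"], "lon": [0.5], "lat": [0.5]})
        table, outside = m.assign_regions(occ, ids, geoms)
        assert outside == 0
        assert table.iloc[0]["region"] == "r00"

    def test_point_outside_all_polygons_is_tallied(self):
        ids, geoms = _regions_from_grid(_grid())
        occ = pd.DataFrame({"species": ["A"], "lon": [5.0], "lat": [5.0]})
        table, outside = m.assign_regions(occ, ids, geoms)
        assert outside == 1 and table.empty

    def test_random_points_match_ray_casting_oracle(self):
        feats = _grid()
        ids, geoms = _regions_from_grid(feats)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-0.5, 2.5, size=(200, 2))
        occ = pd.DataFrame({"species": "A", "lon": pts[:, 0], "lat": pts[:, 1]})
        table, outside = m.assign_regions(occ, ids, geoms)
        got = dict(zip(table["region"], table["count"]))
        expect: dict = {}
        n_out = 0
        for x, y in pts:
            hit = [rid for rid, ring in feats if _ray_cast((x, y), ring)]
            if hit:
                expect[hit[0]] = expect.get(hit[0], 0) + 1
            else:
                n_out += 1
        assert got == expect and outside == n_out


class TestDel:
    def test_single_region(self):
        assign = pd.DataFrame({"species": ["A"] * 10, "region": ["r1"] * 10})
        assert m.count_distinct_regions(assign)["A"] == 1

    def test_three_regions(self):
        assign = pd.DataFrame({"species": ["A"] * 4, "region": ["r1", "r2", "r3", "r1"]})
        assert m.count_distinct_regions(assign)["A"] == 3

    def test_monotone_as_records_accumulate(self):
        rng = np.random.default_rng(9)
        regions = rng.choice([f"r{i}" for i in range(6)], size=40)
        prev = 0
        for k in range(1, 41):
            assign = pd.DataFrame({"species": "A", "region": regions[:k]})
            cur = m.count_distinct_regions(assign)["A"]
            assert cur >= prev
            prev = cur


# ---------------------------------------------------------------------------
# Plasticity


def _frame(values, trait="petiole_length"):
    return pd.DataFrame(
        {
            "species": ["A"] * len(values),
            "specimen_id": [f"s{i}" for i in range(len(values))],
            trait: values,
        }
    )


class TestPlasticity:
    def test_no_variation_gives_zero(self):
        prof = m.compute_plasticity(_frame([5, 5, 5]), traits=("petiole_length",))
        assert prof.total == 0.0

    def test_below_min_n_is_missing(self):
        prof = m.compute_plasticity(_frame([2, 4]), traits=("petiole_length",), min_n=3)
        assert math.isnan(prof.total)

    def test_cv_matches_hand_computation(self):
        # sd([2,4,6], n-1) = 2, mean = 4 -> CV = 0.5
        prof = m.compute_plasticity(_frame([2, 4, 6]), traits=("petiole_length",))
        assert prof.per_trait["petiole_length"] == pytest.approx(0.5)

    def test_total_uses_available_traits_only(self):
        df = _frame([2, 4, 6])
        df["leaf_length"] = [np.nan, np.nan, np.nan]
        prof = m.compute_plasticity(df, traits=("petiole_length", "leaf_length"))
        assert prof.traits_used == ("petiole_length",)
        assert prof.total == pytest.approx(0.5)

    @given(st.floats(min_value=0.01, max_value=1e4), st.integers(0, 1000))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_scale_invariance(self, c, seed):
        vals = np.random.default_rng(seed).uniform(1, 10, size=6)
        a = m.compute_plasticity(_frame(vals), traits=("petiole_length",)).total
        b = m.compute_plasticity(_frame(vals * c), traits=("petiole_length",)).total
        assert b == pytest.approx(a, rel=1e-9)


# ---------------------------------------------------------------------------
# Domatia and interactions


class TestDomatia:
    @pytest.mark.parametrize(
        "codes, expected", [((0, 0, 0), 0), ((2, 2, 2), 6), ((1, 2, 0), 3), ((1, 1, 1), 3)]
    )
    def test_three_specimens_sum(self, codes, expected):
        assert m.score_domatia(codes) == expected

    def test_deficient_specimen_count_rescaled(self):
        assert m.score_domatia([2, 2]) == 6  # mean 2 -> full score
        assert m.score_domatia([1]) == 3

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            m.score_domatia([0, 3, 1])

    def test_total_always_within_range(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            codes = rng.integers(0, 3, size=rng.integers(1, 4))
            assert 0 <= m.score_domatia(list(codes)) <= 6


class TestInteractions:
    def test_distinct_partner_count(self):
        t = pd.DataFrame({"species": ["A"] * 5, "partner": list("vwxyz")})
        assert m.count_interactions(t)["A"] == 5

    def test_duplicates_counted_once(self):
        t = pd.DataFrame({"species": ["A", "A"], "partner": ["w", "w"]})
        assert m.count_interactions(t)["A"] == 1

    def test_randomized_tables_match_set_cardinality_oracle(self):
        rng = np.random.default_rng(8)
        sp = rng.choice(list("ABCD"), 200)
        pa = rng.choice([f"p{i}" for i in range(20)], 200)
        t = pd.DataFrame({"species": sp, "partner": pa})
        got = m.count_interactions(t)
        for s in "ABCD":
            expect = len({p for x, p in zip(sp, pa) if x == s})
            if expect:
                assert got[s] == expect

    def test_absent_species_has_no_value(self):
        t = pd.DataFrame({"species": ["A"], "partner": ["w"]})
        table = m.build_metric_table(interactions=t, domatia=pd.DataFrame(
            {"species": ["A", "A", "A", "B", "B", "B"], "code": [1, 1, 1, 2, 2, 2]}))
        assert math.isnan(table.loc["B", "interactions"])
        assert table.loc["B", "domatia_total"] == 6
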