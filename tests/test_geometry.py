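"""Spherical centroids, haversine distances, natural breaks, distance ranks."""

import itertools
import math

import numpy as np
import pytest

from shorebird_risk.errors import GeometryError, ParameterError
from shorebird_risk.factor_model import FactorKind
from shorebird_risk.geometry import (
    DEFAULT_DISTANCE_BREAKS,
    EARTH_RADIUS_KM,
    DistanceBreaks,
    GeoPoint,
    RangePolygon,
    distance_rank,
    great_circle_km,
    natural_breaks,
    override_rank,
    polygon_from_geojson,
    polygon_to_geojson,
    polygons_from_geojson,
    spherical_centroid,
    spherical_centroid_union,
)


def _quad(lon0, lon1, lat0, lat1):
    return RangePolygon((
        GeoPoint(lon0, lat0), GeoPoint(lon1, lat0),
        GeoPoint(lon1, lat1), GeoPoint(lon0, lat1),
    ))


class TestGreatCircle:
    def test_identity(self):
        p = GeoPoint(-70.5, 42.1)
        assert great_circle_km(p, p) == 0.0

    def test_half_circumference(self):
        assert great_circle_km(GeoPoint(0, 0), GeoPoint(180, 0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM
        )

    def test_one_degree_at_equator(self):
        assert great_circle_km(GeoPoint(0, 0), GeoPoint(1, 0)) == pytest.approx(
            math.pi * EARTH_RADIUS_KM / 180.0
        )

    def test_metric_properties_on_a_point_set(self):
        rng = np.random.default_rng(7)
        pts = [
            GeoPoint(float(lon), float(lat))
            for lon, lat in zip(rng.uniform(-180, 180, 8), rng.uniform(-85, 85, 8))
        ]
        for a, b, c in itertools.permutations(pts, 3):
            dab, dba = great_circle_km(a, b), great_circle_km(b, a)
            assert dab == pytest.approx(dba, abs=1e-6)
            assert dab >= 0
            assert dab <= great_circle_km(a, c) + great_circle_km(c, b) + 1e-6

    def test_coordinates_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            GeoPoint(190.0, 0.0)
        with pytest.raises(GeometryError):
            GeoPoint(0.0, 91.0)


class TestSphericalCentroid:
    def test_tiny_polygon_converges_to_its_location(self):
        tiny = _quad(9.99, 10.01, 19.99, 20.01)
        c = spherical_centroid(tiny)
        assert c.lon == pytest.approx(10.0, abs=1e-3)
        assert c.lat == pytest.approx(20.0, abs=1e-3)

    def test_symmetric_polygon_centers_at_origin(self):
        c = spherical_centroid(_quad(-5, 5, -5, 5))
        assert c.lon == pytest.approx(0.0, abs=1e-9)
        assert c.lat == pytest.approx(0.0, abs=1e-9)

    def test_matches_monte_carlo_surface_sampling(self):
        # mid-latitude 10x10 degree geodesic quad vs. a dense uniform
        # surface-sampling estimate (independent oracle)
        quad = _quad(20.0, 30.0, 35.0, 45.0)
        c = spherical_centroid(quad)

        rng = np.random.default_rng(42)
        n = 400_000
        lon = np.radians(rng.uniform(18.0, 32.0, n))
        sinlat = rng.uniform(math.sin(math.radians(33.0)), math.sin(math.radians(47.0)), n)
        coslat = np.sqrt(1.0 - sinlat**2)
        pts = np.column_stack(
            [coslat * np.cos(lon), coslat * np.sin(lon), sinlat]
        )
        verts = np.array([v.unit_vector() for v in quad.vertices])
        inside = np.ones(n, dtype=bool)
        for i in range(4):  # convex CCW quad: inside = left of every edge
            normal = np.cross(verts[i], verts[(i + 1) % 4])
            inside &= pts @ normal > 0
        mean = pts[inside].mean(axis=0)
        mc = GeoPoint.from_unit_vector(mean / np.linalg.norm(mean))
        assert c.lon == pytest.approx(mc.lon, abs=0.1)
        assert c.lat == pytest.approx(mc.lat, abs=0.1)

    def test_degenerate_polygon_rejected(self):
        sliver = RangePolygon((GeoPoint(0, 0), GeoPoint(10, 0), GeoPoint(5, 0.0)))
        with pytest.raises(GeometryError):
            spherical_centroid(sliver)

    def test_union_weights_parts_by_area(self):
        # a large part dominates a small one on the same parallel
        big = _quad(-10, 10, 30, 50)
        small = _quad(40, 41, 39.5, 40.5)
        c = spherical_centroid_union([big, small])
        alone = spherical_centroid(big)
        assert abs(c.lon - alone.lon) < 1.0
        assert abs(c.lat - alone.lat) < 1.0

    def test_polygon_needs_three_distinct_vertices(self):
        with pytest.raises(GeometryError):
            RangePolygon((GeoPoint(0, 0), GeoPoint(1, 1)))
        with pytest.raises(GeometryError):
            RangePolygon((GeoPoint(0, 0), GeoPoint(0, 0), GeoPoint(1, 1)))


class TestNaturalBreaks:
    def test_two_clusters_split_between_them(self):
        breaks = natural_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert len(breaks.boundaries) == 1
        assert 3 < breaks.boundaries[0] < 10

    def test_forced_split_with_ties(self):
        breaks = natural_breaks([0, 0, 0, 100], k=2)
        assert 0 < breaks.boundaries[0] < 100

    def test_n_equals_k_isolates_every_value(self):
        values = [1.0, 5.0, 9.0, 20.0]
        breaks = natural_breaks(values, k=4)
        assert [distance_rank(v, breaks) for v in values] == [1, 2, 3, 4]

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_partition_oracle(self, k):
        rng = np.random.default_rng(11)
        for _ in range(8):
            n = int(rng.integers(k, 13))
            values = sorted(rng.uniform(0, 1000, n))

            def sse(chunk):
                arr = np.asarray(chunk)
                return float(((arr - arr.mean()) ** 2).sum())

            best = min(
                sum(
                    sse(values[i:j])
                    for i, j in zip((0,) + cuts, cuts + (n,))
                )
                for cuts in itertools.combinations(range(1, n), k - 1)
            )
            breaks = natural_breaks(values, k=k)
            classes = [[v for v in values if distance_rank(v, breaks) == r] for r in range(1, k + 1)]
            assert all(classes), "every class must be non-empty"
            achieved = sum(sse(c) for c in classes)
            assert achieved == pytest.approx(best, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            natural_breaks([1.0, 2.0], k=3)
        with pytest.raises(ParameterError):
            natural_breaks([5.0] * 6, k=2)
        with pytest.raises(ParameterError):
            natural_breaks([1.0, 2.0, 3.0], k=1)


class TestDistanceRank:
    def test_published_worked_example_distance_ranks_4(self):
        assert distance_rank(7886.0, DEFAULT_DISTANCE_BREAKS) == 4

    def test_scale_ends(self):
        assert distance_rank(0.0) == 1
        assert distance_rank(1e9) == 5

    def test_monotone_in_distance(self):
        distances = np.linspace(0, 25000, 400)
        ranks = [distance_rank(d) for d in distances]
        assert ranks == sorted(ranks)

    def test_boundaries_are_half_open_lower_inclusive(self):
        b = DEFAULT_DISTANCE_BREAKS.boundaries[0]
        assert distance_rank(b - 1e-9) == 1
        assert distance_rank(b) == 2

    def test_negative_distance_rejected(self):
        with pytest.raises(ParameterError):
            distance_rank(-1.0)

    def test_breaks_must_increase(self):
        with pytest.raises(ParameterError):
            DistanceBreaks((5.0, 5.0, 7.0, 9.0))


class TestOverrideRank:
    def test_known_distance_override_to_top_rank(self, packaged_profiles):
        godwit = next(p for p in packaged_profiles if p.common_name == "Bar-tailed Godwit")
        overridden = override_rank(godwit, 5)
        level = overridden.levels[FactorKind.MIGRATION_DISTANCE]
        assert (level.score, level.arrows) == (5, 2)

    def test_override_with_current_rank_is_identity(self, packaged_profiles):
        godwit = next(p for p in packaged_profiles if p.common_name == "Bar-tailed Godwit")
        assert override_rank(godwit, 5) is godwit  # already rank 5

    def test_override_changes_are_recorded(self, packaged_profiles):
        killdeer = next(p for p in packaged_profiles if p.common_name == "Killdeer")
        changed = override_rank(killdeer, 5)
        assert "overridden" in (changed.notes or "")

    @pytest.mark.parametrize("bad", [0, 6, 2.5])
    def test_invalid_rank_rejected(self, packaged_profiles, bad):
        with pytest.raises(ParameterError):
            override_rank(packaged_profiles[0], bad)


class TestGeoJSON:
    def test_polygon_round_trip(self):
        poly = _quad(-100, -90, 40, 50)
        again = polygon_from_geojson(polygon_to_geojson(poly))
        assert again == poly

    def test_multipolygon_parsed_to_parts(self):
        geom = {
            "type": "MultiPolygon",
            "coordinates": [
                polygon_to_geojson(_quad(0, 10, 0, 10))["coordinates"],
                polygon_to_geojson(_quad(20, 30, 0, 10))["coordinates"],
            ],
        }
        parts = polygons_from_geojson(geom)
        assert len(parts) == 2

    def test_wrong_geometry_type_rejected(self):
        with pytest.raises(GeometryError):
            polygon_from_geojson({"type": "Point", "coordinates": [0, 0]})
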