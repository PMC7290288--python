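"""Haversine distances, Beringian routing, and ancestry centroids."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import meipop as m
from meipop.geo import EARTH_RADIUS_KM, spherical_centroid

latitudes = st.floats(min_value=-89.9, max_value=89.9)
longitudes = st.floats(min_value=-179.9, max_value=180.0)


class TestHaversine:
    def test_zero_for_identical_points(self):
        assert m.haversine((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_half_circumference(self):
        assert m.haversine((0, 0), (0, 180), radius_km=6371.0) == pytest.approx(
            np.pi * 6371.0, rel=1e-9
        )

    def test_poles_antipodal(self):
        d1 = m.haversine((90, 0), (-90, 0))
        assert d1 == pytest.approx(np.pi * EARTH_RADIUS_KM, rel=1e-9)

    @given(latitudes, longitudes, latitudes, longitudes)
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, lat1, lon1, lat2, lon2):
        assert m.haversine((lat1, lon1), (lat2, lon2)) == pytest.approx(
            m.haversine((lat2, lon2), (lat1, lon1)), abs=1e-6
        )

    def test_out_of_range_errors(self):
        with pytest.raises(m.MEIError):
            m.haversine((91, 0), (0, 0))
        with pytest.raises(m.MEIError):
            m.haversine((0, 0), (0, -180))


class TestBeringianRouting:
    def test_degenerate_legs(self):
        origin = (2.0, 22.0)
        assert m.beringian_distance(origin, m.NAUKAN) == pytest.approx(
            m.haversine(origin, m.NAUKAN)
        )
        dest = (45.0, -100.0)
        assert m.beringian_distance(m.NAUKAN, dest) == pytest.approx(
            m.haversine(m.NAUKAN, dest)
        )

    @given(latitudes, longitudes, latitudes, longitudes)
    @settings(max_examples=50, deadline=None)
    def test_detour_never_shorter(self, lat1, lon1, lat2, lon2):
        a, b = (lat1, lon1), (lat2, lon2)
        assert m.beringian_distance(a, b) >= m.haversine(a, b) - 1e-6


class TestSphericalCentroid:
    def test_single_point(self):
        assert spherical_centroid([(37.5, 126.9)]) == pytest.approx((37.5, 126.9))

    def test_symmetric_pair(self):
        lat, lon = spherical_centroid([(10.0, 0.0), (-10.0, 0.0)])
        assert (lat, lon) == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_antimeridian_wrap(self):
        # naive lon averaging would give 0; the spherical mean stays at 180
        lat, lon = spherical_centroid([(60.0, 175.0), (60.0, -175.0)])
        assert abs(lon) == pytest.approx(180.0, abs=1e-9)

    def test_small_region_matches_planar_mean(self):
        rng = np.random.default_rng(44)
        pts = np.column_stack(
            [50 + rng.uniform(-0.05, 0.05, 30), 90 + rng.uniform(-0.05, 0.05, 30)]
        )
        lat, lon = spherical_centroid(pts)
        err = m.haversine((lat, lon), (pts[:, 0].mean(), pts[:, 1].mean()))
        assert err < 1.0  # km


def ancestry_fixture():
    """Seven-group cohort whose Old World groups ring the planted source."""
    source = (54.0, 91.0)
    ring = {
        "Africa": (67.0, 91.0),
        "West Eurasia": (41.0, 91.0),
        "South Asia": (54.0, 69.0),
        "Central Asia/Siberia": (54.0, 113.0),
        "East Asia": (63.0, 75.0),
        "Oceania": (45.0, 107.0),
        "Americas": (-5.0, -65.0),
    }
    cfg = m.SimConfig(
        seed=11,
        group_sizes={g: (9 if g != "Americas" else 5) for g in ring},
        n_loci={"ALU": 50},
        group_centroids=ring,
        jitter_km=300.0,
        ancestry_source=source,
    )
    calls, panel, anc, truth = m.simulate_cohort(cfg)
    return panel, anc, source


class TestAncestryCentroid:
    def test_single_passing_individual(self):
        frame = pd.DataFrame(
            {
                "sample": ["s1", "s2"],
                "population": ["p", "p"],
                "group": ["East Asia", "East Asia"],
                "lat": [30.0, 50.0],
                "lon": [100.0, 120.0],
            }
        )
        panel = m.SamplePanel(frame)
        anc = m.AncestryTable(
            pd.DataFrame({"k1": [0.5, 0.001], "k2": [0.5, 0.999]}, index=["s1", "s2"])
        )
        lat, lon, table = m.ancestry_centroid(panel, anc, threshold=0.01, component="k1")
        assert (lat, lon) == pytest.approx((30.0, 100.0))
        assert list(table.index) == ["s1"]

    def test_no_passing_individual_errors(self):
        panel, anc, _ = ancestry_fixture()
        with pytest.raises(m.MEIError, match="threshold"):
            m.ancestry_centroid(panel, anc, threshold=0.999, component=0)

    def test_recovers_planted_source(self):
        """With ~50 passing individuals ringing the source, the centroid
        lands within 500 km of it."""
        panel, anc, source = ancestry_fixture()
        lat, lon, table = m.ancestry_centroid(panel, anc, threshold=0.01, component=0)
        assert len(table) >= 50
        assert m.haversine((lat, lon), source) < 500.0

    def test_duplication_invariance(self):
        panel, anc, _ = ancestry_fixture()
        lat, lon, _ = m.ancestry_centroid(panel, anc, threshold=0.01, component=0)
        doubled = m.SamplePanel(
            pd.concat(
                [
                    panel.frame,
                    panel.frame.assign(sample=panel.frame["sample"] + "_dup"),
                ]
            )
        )
        frame2 = anc.frame.copy()
        dup = anc.frame.copy()
        dup.index = dup.index + "_dup"
        anc2 = m.AncestryTable(pd.concat([frame2, dup]))
        lat2, lon2, _ = m.ancestry_centroid(doubled, anc2, threshold=0.01, component=0)
        assert (lat2, lon2) == pytest.approx((lat, lon), abs=1e-9)

    def test_threshold_moves_centroid_toward_source(self, structured_cohort):
        """On the world-map cohort, raising the threshold from 1% to 6.25%
        pulls the centroid toward the high-ancestry pole."""
        panel, anc, truth = (
            structured_cohort["panel"],
            structured_cohort["anc"],
            structured_cohort["truth"],
        )
        source = truth["ancestry_source"]
        lat1, lon1, _ = m.ancestry_centroid(panel, anc, threshold=0.01, component=0)
        lat2, lon2, _ = m.ancestry_centroid(panel, anc, threshold=0.0625, component=0)
        assert m.haversine((lat2, lon2), source) < m.haversine((lat1, lon1), source)

    def test_old_world_only_excludes_americas(self):
        panel, anc, _ = ancestry_fixture()
        _, _, table = m.ancestry_centroid(panel, anc, threshold=0.01, component=0)
        assert not (table["group"] == "Americas").any()
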