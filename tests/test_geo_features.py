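import numpy as np
import pandas as pd
import pytest
from shapely import LineString, Point

from monnet import (GeoFeatureMatrix, VariableMeta, density_variable,
                    exclude_low_variability, proximity_variable,
                    recode_proximity, zscale)
from monnet.geo_features import apply_scaling
from monnet.synthetic_city import LineSource, PointSource, SourceSet


def loc_frame(coords):
    xs, ys = zip(*coords)
    return pd.DataFrame({"id": [f"L{i}" for i in range(len(xs))],
                         "x": xs, "y": ys})


class TestProximity:
    def test_coincident_point_source(self):
        src = SourceSet(points=[PointSource(10.0, 20.0, "bus_stop")])
        d = proximity_variable(loc_frame([(10.0, 20.0)]), src, "bus_stop")
        assert d.iloc[0] == 0.0

    def test_nearest_of_two_points(self):
        src = SourceSet(points=[PointSource(3, 4, "bus_stop"),
                                PointSource(6, 8, "bus_stop")])
        d = proximity_variable(loc_frame([(0.0, 0.0)]), src, "bus_stop")
        assert d.iloc[0] == pytest.approx(5.0)

    def test_segment_distance_is_to_nearest_point_on_segment(self):
        src = SourceSet(line_segments=[LineSource(0, 0, 10, 0, "major_road")])
        d = proximity_variable(
            loc_frame([(5.0, 3.0), (20.0, 0.0)]), src, "major_road")
        assert d.iloc[0] == pytest.approx(3.0)   # perpendicular foot inside
        assert d.iloc[1] == pytest.approx(10.0)  # beyond the endpoint

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(0)
        src = SourceSet(
            line_segments=[LineSource(*rng.uniform(0, 1000, 4), "major_road")
                           for _ in range(12)],
            points=[PointSource(*rng.uniform(0, 1000, 2), "major_road")
                    for _ in range(8)])
        locs = loc_frame(rng.uniform(0, 1000, (50, 2)))
        d = proximity_variable(locs, src, "major_road")
        geoms = ([LineString([(s.x1, s.y1), (s.x2, s.y2)])
                  for s in src.line_segments]
                 + [Point(p.x, p.y) for p in src.points])
        for i, (_, row) in enumerate(locs.iterrows()):
            brute = min(g.distance(Point(row["x"], row["y"])) for g in geoms)
            assert d.iloc[i] == pytest.approx(brute)

    def test_no_sources_of_kind(self):
        with pytest.raises(ValueError, match="no sources"):
            proximity_variable(loc_frame([(0, 0)]), SourceSet(), "bus_stop")


class TestDensity:
    def test_nothing_within_radius(self):
        src = SourceSet(points=[PointSource(5000, 5000, "construction")])
        d = density_variable(loc_frame([(0, 0)]), src, "construction", 100.0)
        assert d.iloc[0] == 0.0

    def test_point_count_within_radius(self):
        src = SourceSet(points=[PointSource(10, 0, "b"), PointSource(0, 50, "b"),
                                PointSource(500, 0, "b")])
        d = density_variable(loc_frame([(0, 0)]), src, "b", 100.0)
        assert d.iloc[0] == 2.0

    def test_chord_through_buffer_center(self):
        src = SourceSet(
            line_segments=[LineSource(-1000, 0, 1000, 0, "major_road")])
        d = density_variable(loc_frame([(0, 0)]), src, "major_road", 250.0)
        assert d.iloc[0] == pytest.approx(500.0, rel=1e-3)

    def test_clipped_length_matches_dense_sampling(self):
        rng = np.random.default_rng(1)
        segs = [LineSource(*rng.uniform(0, 2000, 4), "major_road")
                for _ in range(10)]
        src = SourceSet(line_segments=segs)
        locs = loc_frame(rng.uniform(0, 2000, (20, 2)))
        radius = 300.0
        d = density_variable(locs, src, "major_road", radius)
        for i, (_, row) in enumerate(locs.iterrows()):
            total = 0.0
            for s in segs:  # numeric integration: dense sampling per segment
                p0 = np.array([s.x1, s.y1])
                p1 = np.array([s.x2, s.y2])
                length = np.linalg.norm(p1 - p0)
                t = np.linspace(0, 1, 20001)
                pts = p0 + t[:, None] * (p1 - p0)
                inside = (np.hypot(pts[:, 0] - row["x"],
                                   pts[:, 1] - row["y"]) <= radius)
                total += length * inside.mean()
            assert d.iloc[i] == pytest.approx(total, rel=0.01, abs=1.0)

    def test_nonpositive_radius_rejected(self):
        src = SourceSet(points=[PointSource(0, 0, "b")])
        with pytest.raises(ValueError, match="radius"):
            density_variable(loc_frame([(0, 0)]), src, "b", 0.0)


class TestRecodeProximity:
    def test_truncation_binds_beyond_cap(self):
        out = recode_proximity(np.array([5000.0]), cap=1000.0, eps=1.0)
        assert out[0] == pytest.approx(np.log(1001.0))

    def test_zero_distance_maps_to_zero(self):
        assert recode_proximity(np.array([0.0]), eps=1.0)[0] == 0.0

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(2)
        col = np.sort(rng.uniform(0, 3000, 200))
        out = recode_proximity(col, cap=1000.0)
        expected = np.log(np.minimum(col, 1000.0) + 1.0)
        np.testing.assert_allclose(out, expected)
        assert (np.diff(out) >= 0).all()
        assert out.max() <= np.log(1001.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            recode_proximity(np.array([-1.0]))


class TestExcludeLowVariability:
    @staticmethod
    def matrix(values: dict, land_use: set = frozenset()):
        df = pd.DataFrame(values)
        meta = {c: VariableMeta(name=c, land_use_flag=c in land_use,
                                category="land use" if c in land_use
                                else "traffic")
                for c in df.columns}
        return GeoFeatureMatrix(values=df, meta=meta, state="recoded")

    def test_constant_column_dropped(self):
        m = self.matrix({"const": np.ones(50),
                         "varied": np.arange(50.0)})
        out, report = exclude_low_variability(m)
        assert out.variables == ["varied"]
        assert report.loc[0, "reason"] == "low_unique"

    def test_low_land_use_share_dropped(self):
        rng = np.random.default_rng(3)
        m = self.matrix({"water": rng.uniform(0, 8, 50),
                         "roads": rng.uniform(0, 80, 50)},
                        land_use={"water", "roads"})
        out, report = exclude_low_variability(m)
        assert out.variables == ["roads"]
        assert report.loc[0, "reason"] == "low_land_use_share"

    def test_distinct_non_land_use_always_kept(self):
        rng = np.random.default_rng(4)
        m = self.matrix({f"v{i}": rng.normal(size=40) for i in range(5)})
        out, report = exclude_low_variability(m)
        assert out.variables == m.variables
        assert report.empty


class TestZScale:
    def test_three_point_column(self):
        m = GeoFeatureMatrix(values=pd.DataFrame({"v": [1.0, 2.0, 3.0]}))
        scaled, stats = zscale(m)
        np.testing.assert_allclose(scaled.values["v"], [-1.0, 0.0, 1.0])
        assert stats.loc["v", "mean"] == 2.0
        assert stats.loc["v", "sd"] == 1.0

    def test_idempotent_on_scaled_column(self):
        rng = np.random.default_rng(5)
        col = rng.normal(size=100)
        col = (col - col.mean()) / col.std(ddof=1)
        m = GeoFeatureMatrix(values=pd.DataFrame({"v": col}))
        scaled, _ = zscale(m)
        np.testing.assert_allclose(scaled.values["v"], col, atol=1e-12)

    def test_output_moments_and_roundtrip(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.gamma(2, 3, size=(200, 4)),
                          columns=list("abcd"))
        m = GeoFeatureMatrix(values=df)
        scaled, stats = zscale(m)
        assert np.abs(scaled.values.mean()).max() < 1e-8
        assert np.abs(scaled.values.std(ddof=1) - 1).max() < 1e-8
        back = scaled.values * stats["sd"] + stats["mean"]
        np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-8)

    def test_apply_scaling_reuses_statistics(self):
        rng = np.random.default_rng(7)
        train = GeoFeatureMatrix(
            values=pd.DataFrame({"v": rng.normal(10, 2, 50)}))
        _, stats = zscale(train)
        new = GeoFeatureMatrix(values=pd.DataFrame({"v": [10.0]}))
        out = apply_scaling(new, stats)
        expected = (10.0 - stats.loc["v", "mean"]) / stats.loc["v", "sd"]
        assert out.values["v"].iloc[0] == pytest.approx(expected)

    def test_zero_sd_column_rejected(self):
        m = GeoFeatureMatrix(values=pd.DataFrame({"c": np.ones(10)}))
        with pytest.raises(ValueError, match="zero-SD"):
            zscale(m)
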