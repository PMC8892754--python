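"""Stopover detection by the 35 km daily-displacement rule and segment extraction."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ternflight import segmentation as seg
from ternflight import synthetic as syn
from ternflight.geo import destination


def _track_from_daily_displacements(disps, lon0=10.0, lat0=40.0):
    """Two fixes per day; the day's last fix advances by the given net km."""
    rows = []
    lon, lat = lon0, lat0
    for d, km in enumerate(disps):
        day = pd.Timestamp("2021-09-01", tz="UTC") + pd.Timedelta(days=d)
        rows.append({"individual_id": "b1", "timestamp": day + pd.Timedelta(hours=6),
                     "lon": lon, "lat": lat})
        lon, lat = destination(lon, lat, 180.0, km)
        rows.append({"individual_id": "b1", "timestamp": day + pd.Timedelta(hours=18),
                     "lon": lon, "lat": lat})
    return pd.DataFrame(rows)


class TestDailyDisplacement:
    def test_stationary_day_zero(self):
        df = _track_from_daily_displacements([0.0, 0.0])
        disp = seg.daily_displacement(df)
        assert disp["displacement_km"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_net_displacement_measured(self):
        df = _track_from_daily_displacements([0.0, 40.0])
        disp = seg.daily_displacement(df)
        assert disp["displacement_km"].iloc[1] == pytest.approx(40.0, rel=1e-6)

    def test_loop_counts_net_not_path(self):
        # 200 km out and back within the day, ending 10 km from yesterday
        day0 = pd.Timestamp("2021-09-01", tz="UTC")
        lon1, lat1 = destination(10.0, 40.0, 90.0, 200.0)
        lon2, lat2 = destination(10.0, 40.0, 180.0, 10.0)
        df = pd.DataFrame([
            {"individual_id": "b1", "timestamp": day0, "lon": 10.0, "lat": 40.0},
            {"individual_id": "b1", "timestamp": day0 + pd.Timedelta(days=1, hours=6),
             "lon": lon1, "lat": lat1},
            {"individual_id": "b1", "timestamp": day0 + pd.Timedelta(days=1, hours=20),
             "lon": lon2, "lat": lat2},
        ])
        disp = seg.daily_displacement(df)
        assert disp["displacement_km"].iloc[-1] == pytest.approx(10.0, rel=1e-6)


class TestDetectStopovers:
    def test_interior_two_day_stopover(self):
        df = _track_from_daily_displacements([300, 10, 5, 280])
        st = seg.detect_stopovers(df)
        assert len(st) == 1
        assert st[0].duration_days == 2
        assert st[0].start_date == dt.date(2021, 9, 2)

    def test_exactly_35_km_is_a_stopover_day(self):
        df = _track_from_daily_displacements([300, 35.0, 280])
        st = seg.detect_stopovers(df)
        assert len(st) == 1
        assert st[0].start_date == dt.date(2021, 9, 2)

    def test_all_fast_days_no_stopover(self):
        df = _track_from_daily_displacements([300, 200, 280])
        assert seg.detect_stopovers(df) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        df = _track_from_daily_displacements(rng.uniform(0, 120, 20))
        days_at = {}
        for thr in (20.0, 35.0, 60.0):
            days_at[thr] = sum(s.duration_days
                               for s in seg.detect_stopovers(df, threshold_km=thr))
        assert days_at[20.0] <= days_at[35.0] <= days_at[60.0]


class TestExtractSegments:
    def test_interior_stopover_splits_in_two(self):
        df = _track_from_daily_displacements([300, 10, 5, 280, 290])
        st = seg.detect_stopovers(df)
        segs = seg.extract_segments(df, st)
        assert len(segs) == 2
        assert segs[0].end_date == dt.date(2021, 9, 1)
        assert segs[1].start_date == dt.date(2021, 9, 4)

    def test_stopover_at_track_end(self):
        df = _track_from_daily_displacements([300, 280, 5, 5])
        st = seg.detect_stopovers(df)
        segs = seg.extract_segments(df, st)
        assert len(segs) == 1
        assert segs[0].end_date == dt.date(2021, 9, 2)

    def test_covariates_from_schedule(self, processed_track):
        st = seg.detect_stopovers(processed_track)
        segs = seg.extract_segments(processed_track, st, staging_days=5.0)
        assert [s.days_of_migration for s in segs] == [0, 5]
        assert segs[0].days_at_previous_stopover == 5.0   # staging metadata
        assert segs[1].days_at_previous_stopover == 2.0   # the implanted stopover

    def test_spring_has_no_previous_stopover_covariate(self, processed_track):
        st = seg.detect_stopovers(processed_track)
        segs = seg.extract_segments(processed_track, st, season="spring")
        assert all(s.days_at_previous_stopover is None for s in segs)

    def test_partition_of_migration_days(self, processed_track):
        st = seg.detect_stopovers(processed_track)
        segs = seg.extract_segments(processed_track, st)
        covered = set()
        for s in st:
            d = s.start_date
            while d <= s.end_date:
                assert d not in covered
                covered.add(d)
                d += dt.timedelta(days=1)
        for s in segs:
            d = s.start_date
            while d <= s.end_date:
                assert d not in covered
                covered.add(d)
                d += dt.timedelta(days=1)
        all_days = set(processed_track["timestamp"].dt.tz_convert("UTC").dt.date)
        assert covered == all_days


class TestRoundTrip:
    def test_noiseless_recovery_exact(self, std_track, processed_track):
        _, truth = std_track
        st = seg.detect_stopovers(processed_track)
        t0 = dt.date(2021, 9, 1)
        recovered = set()
        for s in st:
            d = s.start_date
            while d <= s.end_date:
                recovered.add((d - t0).days)
                d += dt.timedelta(days=1)
        assert recovered == set(truth.stopover_days)

    def test_noisy_recovery_above_95_percent(self, coarse_landscape):
        agree = total = 0
        for i in range(10):
            spec = syn.TrackSpec(seed=200 + i, n_days=10,
                                 stopover_schedule=((2, 2), (6, 1)),
                                 start=(11.0, 21.5), heading=180.0,
                                 cruise_speed=25.0, flight_prob_day=1.0,
                                 flight_prob_night=0.0, position_noise_km=1.0)
            fixes, truth = syn.generate_track(spec, coarse_landscape)
            st = seg.detect_stopovers(fixes)
            t0 = dt.date(2021, 9, 1)
            rec = set()
            for s in st:
                d = s.start_date
                while d <= s.end_date:
                    rec.add((d - t0).days)
                    d += dt.timedelta(days=1)
            truth_set = set(truth.stopover_days)
            for day in range(spec.n_days):
                total += 1
                agree += (day in rec) == (day in truth_set)
        assert agree / total >= 0.95


class TestRegions:
    REGIONS = {"type": "FeatureCollection", "features": [
        {"type": "Feature", "properties": {"label": "west"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[0, 0], [5, 0], [5, 10], [0, 10], [0, 0]]]}},
        {"type": "Feature", "properties": {"label": "east"},
         "geometry": {"type": "Polygon",
                      "coordinates": [[[5, 0], [10, 0], [10, 10], [5, 10], [5, 0]]]}},
    ]}

    def _segment(self, lons):
        fixes = pd.DataFrame({
            "individual_id": "b1",
            "timestamp": pd.date_range("2021-09-01", periods=len(lons),
                                       freq="30min", tz="UTC"),
            "lon": lons, "lat": 5.0})
        return seg.TravelingSegment("b1", dt.date(2021, 9, 1), dt.date(2021, 9, 1),
                                    fixes)

    def test_all_fixes_one_polygon(self):
        regions = seg.load_regions(self.REGIONS)
        assert seg.assign_region(self._segment([1, 2, 3]), regions) == "west"

    def test_majority_rule(self):
        regions = seg.load_regions(self.REGIONS)
        assert seg.assign_region(self._segment([1, 2, 3, 7, 8]), regions) == "west"
        assert seg.assign_region(self._segment([1, 2, 7, 8, 9]), regions) == "east"

    def test_no_overlap_unassigned(self):
        regions = seg.load_regions(self.REGIONS)
        assert seg.assign_region(self._segment([20, 21]), regions) == "unassigned"

    def test_invalid_region_file_raises(self, tmp_path):
        p = tmp_path / "bad.geojson"
        p.write_text("{not json")
        with pytest.raises(ValueError):
            seg.load_regions(p)
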