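"""Stopover detection and traveling-segment extraction.

A stopover is a maximal run of calendar days (UTC by default) on which the
bird did not advance more than 35 km between last daily relocations — net
displacement, not path length. Traveling segments are the maximal runs of
remaining days; the covariates days-of-migration and days-at-previous-
stopover are attached here.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import haversine_km

STOPOVER_THRESHOLD_KM = 35.0


@dataclass
class Stopover:
    individual_id: str
    start_date: dt.date
    end_date: dt.date           # inclusive
    lon: float                  # centroid of member fixes
    lat: float

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass
class TravelingSegment:
    individual_id: str
    start_date: dt.date
    end_date: dt.date           # inclusive
    fixes: pd.DataFrame = field(repr=False)
    season: str = "autumn"
    days_of_migration: int = 0
    days_at_previous_stopover: float | None = None
    region: str | None = None

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def daily_displacement(df: pd.DataFrame) -> pd.DataFrame:
    """Net km between last daily relocations, per individual and UTC date.

    The first day of a track is measured from the track's first fix. Days
    with no fixes are absent from the table.
    """
    rows = []
    for ind, g in df.groupby("individual_id", sort=False):
        g = g.sort_values("timestamp")
        dates = g["timestamp"].dt.tz_convert("UTC").dt.date
        last = g.groupby(dates.values).tail(1)
        lons = last["lon"].to_numpy()
        lats = last["lat"].to_numpy()
        ref_lon = np.concatenate([[g["lon"].iloc[0]], lons[:-1]])
        ref_lat = np.concatenate([[g["lat"].iloc[0]], lats[:-1]])
        disp = haversine_km(ref_lon, ref_lat, lons, lats)
        day_list = last["timestamp"].dt.tz_convert("UTC").dt.date.to_numpy()
        for d, km in zip(day_list, disp):
            rows.append({"individual_id": ind, "date": d, "displacement_km": float(km)})
    return pd.DataFrame(rows, columns=["individual_id", "date", "displacement_km"])


def _classify_days(disp: pd.DataFrame, threshold_km: float):
    """Full-calendar day classification; gap days inherit the preceding class."""
    out = {}
    for ind, g in disp.groupby("individual_id", sort=False):
        g = g.sort_values("date")
        d0, d1 = g["date"].iloc[0], g["date"].iloc[-1]
        lookup = dict(zip(g["date"], g["displacement_km"] <= threshold_km))
        days, classes = [], []
        cur = None
        d = d0
        while d <= d1:
            if d in lookup:
                cur = lookup[d]
            days.append(d)
            classes.append(bool(cur))
            d += dt.timedelta(days=1)
        out[ind] = (days, classes)
    return out


def detect_stopovers(df: pd.DataFrame, threshold_km: float = STOPOVER_THRESHOLD_KM,
                     disp: pd.DataFrame | None = None) -> list[Stopover]:
    """Maximal runs of days with net displacement <= threshold (inclusive)."""
    if disp is None:
        disp = daily_displacement(df)
    stopovers = []
    for ind, (days, classes) in _classify_days(disp, threshold_km).items():
        g = df[df["individual_id"] == ind]
        gdates = g["timestamp"].dt.tz_convert("UTC").dt.date
        i = 0
        while i < len(days):
            if classes[i]:
                j = i
                while j + 1 < len(days) and classes[j + 1]:
                    j += 1
                member = g[(gdates >= days[i]) & (gdates <= days[j])]
                stopovers.append(Stopover(
                    individual_id=ind, start_date=days[i], end_date=days[j],
                    lon=float(member["lon"].mean()) if len(member) else np.nan,
                    lat=float(member["lat"].mean()) if len(member) else np.nan))
                i = j + 1
            else:
                i += 1
    return stopovers


def extract_segments(df: pd.DataFrame, stopovers: list[Stopover],
                     season: str = "autumn",
                     staging_days: dict | float | None = None,
                     threshold_km: float = STOPOVER_THRESHOLD_KM,
                     disp: pd.DataFrame | None = None) -> list[TravelingSegment]:
    """Traveling segments = maximal travel-day runs between stopovers.

    days_of_migration counts days since the first day of the track (0-based
    at migration start). days_at_previous_stopover is the duration of the
    immediately preceding stopover; the first autumn segment uses the
    pre-departure staging duration from ``staging_days`` (a scalar, or a
    mapping individual_id -> days). Spring segments carry None: fuelling
    before spring departure happens inside the wintering range, where
    staging durations are not observable from the migratory track.
    """
    if disp is None:
        disp = daily_displacement(df)
    by_ind: dict = {}
    for s in stopovers:
        by_ind.setdefault(s.individual_id, []).append(s)
    segments = []
    for ind, (days, classes) in _classify_days(disp, threshold_km).items():
        g = df[df["individual_id"] == ind]
        gdates = g["timestamp"].dt.tz_convert("UTC").dt.date
        stops = sorted(by_ind.get(ind, []), key=lambda s: s.start_date)
        if isinstance(staging_days, dict):
            stage = staging_days.get(ind)
        else:
            stage = staging_days
        start_of_track = days[0]
        i = 0
        while i < len(days):
            if not classes[i]:
                j = i
                while j + 1 < len(days) and not classes[j + 1]:
                    j += 1
                fixes = g[(gdates >= days[i]) & (gdates <= days[j])]
                prev = [s for s in stops if s.end_date < days[i]]
                if season == "spring":
                    at_prev = None
                elif prev:
                    at_prev = float(prev[-1].duration_days)
                else:
                    at_prev = float(stage) if stage is not None else None
                segments.append(TravelingSegment(
                    individual_id=ind, start_date=days[i], end_date=days[j],
                    fixes=fixes.reset_index(drop=True), season=season,
                    days_of_migration=(days[i] - start_of_track).days,
                    days_at_previous_stopover=at_prev))
                i = j + 1
            else:
                i += 1
    return segments


def load_regions(path) -> list[tuple[str, object]]:
    """Read a GeoJSON FeatureCollection of region polygons.

    Each feature needs a ``label`` (or ``name``) property.
    """
    from shapely.geometry import shape
    try:
        gj = json.loads(open(path).read()) if not isinstance(path, dict) else path
    except (json.JSONDecodeError, OSError) as e:
        raise ValueError(f"invalid region polygon file: {e}") from e
    regions = []
    for feat in gj.get("features", []):
        label = feat.get("properties", {}).get("label") or \
            feat.get("properties", {}).get("name") or "unnamed"
        regions.append((label, shape(feat["geometry"])))
    if not regions:
        raise ValueError("region file contains no polygon features")
    return regions


def assign_region(segment: TravelingSegment, regions) -> str:
    """Label of the polygon containing the majority of the segment's fixes."""
    from shapely.geometry import Point
    counts = {label: 0 for label, _ in regions}
    for lon, lat in zip(segment.fixes["lon"], segment.fixes["lat"]):
        p = Point(lon, lat)
        for label, geom in regions:
            if geom.contains(p):
                counts[label] += 1
                break
    best = max(counts, key=counts.get) if counts else None
    if best is None or counts[best] == 0:
        return "unassigned"
    return best
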