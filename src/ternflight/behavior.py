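"""The five traveling-behavior metrics per segment.

travel speed (km/day), median flight height above ground (m), mean daily
flight hours, mean day/night flight ratio (photoperiod-corrected), and the
straightness index (beeline / path length, in (0, 1]). Percentage change
from the individual seasonal mean summarizes within-individual variation.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import solar
from .geo import haversine_km, path_length_km
from .raster import Raster
from .segmentation import TravelingSegment

#: hours substituted for zero day- or night-flight when forming the ratio
RATIO_CONTINUITY_H = 0.25   # half of one 30-min interval


def _dates(fixes: pd.DataFrame):
    return fixes["timestamp"].dt.tz_convert("UTC").dt.date


def travel_speed_kmday(segment: TravelingSegment) -> float:
    """Cumulative path length over consecutive fixes / number of segment days."""
    fixes = segment.fixes
    if len(fixes) < 2:
        raise ValueError("travel speed needs at least two relocations")
    n_days = _dates(fixes).nunique()
    if n_days == 0:
        raise ValueError("zero-duration segment")
    return path_length_km(fixes["lon"].to_numpy(), fixes["lat"].to_numpy()) / n_days


def flight_heights_agl(segment: TravelingSegment, dem: Raster) -> np.ndarray:
    """Per-fix height above ground for flight-classified fixes.

    GPS altitude minus DEM elevation; negative heights are retained (they
    are real low flights or benign GPS error, and dropping them would bias
    the median upward). Fixes outside the DEM are excluded.
    """
    f = segment.fixes
    fl = f[f.get("in_flight_fix", pd.Series(False, index=f.index)).astype(bool)]
    if fl.empty or "gps_altitude" not in fl.columns:
        return np.array([])
    ground = np.asarray(dem.sample_bilinear(fl["lon"].to_numpy(), fl["lat"].to_numpy()))
    ok = ground != dem.nodata
    return (pd.to_numeric(fl["gps_altitude"], errors="coerce").to_numpy()[ok]
            - ground[ok])


def median_flight_height(segment: TravelingSegment, dem: Raster) -> float:
    h = flight_heights_agl(segment, dem)
    return float(np.median(h)) if h.size else np.nan


def daily_flight_hours(segment: TravelingSegment) -> pd.Series:
    """0.5 h per flight interval, summed per UTC date."""
    f = segment.fixes
    by_day = f.groupby(_dates(f).values)["flight"].sum() * 0.5
    return by_day.astype(float)


def mean_daily_flight_hours(segment: TravelingSegment) -> float:
    h = daily_flight_hours(segment)
    return float(h.mean()) if len(h) else np.nan


def _split_flight_hours(day_fixes: pd.DataFrame) -> tuple[float, float]:
    """(day, night) flight hours for one date; dawn_dusk intervals are
    apportioned by the sun's side of the horizon at the interval midpoint."""
    day_h = night_h = 0.0
    fl = day_fixes[day_fixes["flight"].astype(bool)]
    for _, row in fl.iterrows():
        ph = row["phase"]
        if ph == solar.DAY:
            day_h += 0.5
        elif ph == solar.NIGHT:
            night_h += 0.5
        else:
            mid = row["timestamp"] + pd.Timedelta(minutes=15)
            if solar.is_daylight(row["lon"], row["lat"], mid.to_pydatetime()):
                day_h += 0.5
            else:
                night_h += 0.5
    return day_h, night_h


def day_night_ratio(segment: TravelingSegment,
                    continuity_h: float = RATIO_CONTINUITY_H) -> float:
    """Mean over days of (day flight h / daylight h) / (night flight h / dark h).

    Values above 1 indicate predominantly diurnal migratory flight. Zero
    day- or night-flight hours are replaced by ``continuity_h`` so per-day
    ratios stay finite; polar days (no daylight or no dark) are excluded.
    """
    f = segment.fixes
    ratios = []
    for date, g in f.groupby(_dates(f).values):
        daylight = float(g["daylight_h"].iloc[0])
        dark = float(g["dark_h"].iloc[0])
        if daylight <= 0.0 or dark <= 0.0:
            continue
        day_h, night_h = _split_flight_hours(g)
        day_h = day_h if day_h > 0 else continuity_h
        night_h = night_h if night_h > 0 else continuity_h
        ratios.append((day_h / daylight) / (night_h / dark))
    return float(np.mean(ratios)) if ratios else np.nan


def straightness(segment: TravelingSegment) -> float:
    """Beeline distance / path length; 1 = perfectly straight, 0 for a closed loop."""
    f = segment.fixes
    if len(f) < 2:
        raise ValueError("straightness undefined for a single-fix segment")
    path = path_length_km(f["lon"].to_numpy(), f["lat"].to_numpy())
    if path == 0.0:
        return np.nan
    bee = float(haversine_km(f["lon"].iloc[0], f["lat"].iloc[0],
                             f["lon"].iloc[-1], f["lat"].iloc[-1]))
    return min(bee / path, 1.0)


def percent_change(values: pd.Series, groups: pd.Series | None = None) -> pd.Series:
    """100 * (value - group mean) / group mean, per individual-season group.

    With no ``groups``, all values form one group. Zero group means yield
    NaN (flagged as undefined rather than raising).
    """
    values = pd.Series(values, dtype=float)
    if groups is None:
        groups = pd.Series(0, index=values.index)
    means = values.groupby(groups.values).transform("mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (values - means) / means
    out[means == 0] = np.nan
    return out


def compute_segment_behaviors(segments: list[TravelingSegment],
                              dem: Raster | None = None) -> pd.DataFrame:
    """One row per segment with the five metrics and segmentation covariates."""
    rows = []
    for i, seg in enumerate(segments):
        rows.append({
            "segment_id": i,
            "individual_id": seg.individual_id,
            "season": seg.season,
            "start_date": seg.start_date,
            "n_days": seg.n_days,
            "days_of_migration": seg.days_of_migration,
            "days_at_previous_stopover": seg.days_at_previous_stopover,
            "region": seg.region,
            "travel_speed_kmday": travel_speed_kmday(seg) if len(seg.fixes) > 1 else np.nan,
            "median_flight_height_m": (median_flight_height(seg, dem)
                                       if dem is not None else np.nan),
            "mean_daily_flight_hours": mean_daily_flight_hours(seg),
            "mean_day_night_ratio": (day_night_ratio(seg)
                                     if "phase" in seg.fixes.columns else np.nan),
            "straightness": straightness(seg) if len(seg.fixes) > 1 else np.nan,
        })
    return pd.DataFrame(rows)
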