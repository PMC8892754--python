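"""Track ingestion, quality filtering, 30-min resampling and flight/phase classification.

The in-memory representation is a tidy DataFrame (one row per fix) with
columns ``individual_id, timestamp (UTC), lon, lat, gps_altitude,
instant_speed_kmh`` plus columns added by the processing steps:

- ``slot``: the 30-min slot a resampled fix represents
- ``step_kmh`` / ``bearing``: speed and bearing of the step ending at a fix
- ``flight``: True where the 30-min interval *starting* at this fix is a
  migratory flight (ground speed > 10 km/h at both endpoints)
- ``in_flight_fix``: fix participates in at least one flight interval
- ``phase``: day / night / dawn_dusk; ``daylight_h`` / ``dark_h`` per date
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import solar
from .geo import haversine_km, initial_bearing_deg
from .synthetic import MOVEBANK_COLUMNS

log = logging.getLogger(__name__)

FLIGHT_SPEED_KMH = 10.0   # strict ">": exactly 10 km/h is stationary
REQUIRED = ("individual_id", "timestamp", "lon", "lat")


def read_tracks(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a Movebank-style CSV into the tidy fix table.

    ``column_map`` maps internal names to CSV column names; defaults to the
    Movebank dialect. Malformed rows (unparseable timestamp, lat/lon out of
    bounds) are dropped with a log message; duplicate (individual,
    timestamp) rows keep the first occurrence.
    """
    cmap = dict(MOVEBANK_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for k, v in cmap.items() if k in REQUIRED and v not in raw.columns]
    if missing:
        raise ValueError(f"required columns missing from {path}: {missing}")
    df = pd.DataFrame()
    for internal, csv_name in cmap.items():
        if csv_name in raw.columns:
            df[internal] = raw[csv_name]
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    if "instant_speed_kmh" in df.columns:
        df["instant_speed_kmh"] = pd.to_numeric(df["instant_speed_kmh"],
                                                errors="coerce") * 3.6  # m/s -> km/h
    n0 = len(df)
    bad = (df["timestamp"].isna() | df["lon"].isna() | df["lat"].isna()
           | (df["lat"].abs() > 90.0) | (df["lon"].abs() > 180.0))
    if bad.any():
        log.warning("dropping %d malformed rows", int(bad.sum()))
    df = df[~bad]
    df = df.sort_values(["individual_id", "timestamp"])
    dups = df.duplicated(subset=["individual_id", "timestamp"])
    if dups.any():
        log.warning("dropping %d duplicate-timestamp rows", int(dups.sum()))
    df = df[~dups]
    log.info("read %d fixes (%d dropped)", len(df), n0 - len(df))
    return df.reset_index(drop=True)


def _per_individual(df):
    for ind, g in df.groupby("individual_id", sort=False):
        yield ind, g.sort_values("timestamp")


def quality_filter(df: pd.DataFrame, max_speed_kmh: float = 150.0,
                   max_climb_ms: float = 20.0) -> pd.DataFrame:
    """Iteratively drop fixes implying impossible speeds or climb rates.

    A fix whose step from the previous retained fix implies ground speed
    above ``max_speed_kmh`` or |climb rate| above ``max_climb_ms`` is
    removed; passes repeat until no offender remains.
    """
    kept = []
    for ind, g in _per_individual(df):
        g = g.reset_index(drop=True)
        while len(g) > 1:
            t = g["timestamp"].astype("int64").to_numpy() / 1e9
            dt_h = np.diff(t) / 3600.0
            dt_h[dt_h <= 0] = np.nan
            spd = haversine_km(g["lon"].to_numpy()[:-1], g["lat"].to_numpy()[:-1],
                               g["lon"].to_numpy()[1:], g["lat"].to_numpy()[1:]) / dt_h
            bad = spd > max_speed_kmh
            if "gps_altitude" in g.columns:
                alt = pd.to_numeric(g["gps_altitude"], errors="coerce").to_numpy()
                climb = np.abs(np.diff(alt)) / (dt_h * 3600.0)
                bad = bad | (climb > max_climb_ms)
            bad_idx = np.flatnonzero(np.nan_to_num(bad.astype(float)) > 0)
            if bad_idx.size == 0:
                break
            # remove the single worst offender, then re-evaluate: a spike fix
            # makes both its inbound and outbound steps impossible, and only
            # the fix itself should go
            worst = bad_idx[np.argmax(np.nan_to_num(spd[bad_idx]))]
            g = g.drop(index=worst + 1).reset_index(drop=True)
        kept.append(g)
    return pd.concat(kept, ignore_index=True) if kept else df.iloc[0:0]


def resample_30min(df: pd.DataFrame, tolerance_min: float = 5.0) -> pd.DataFrame:
    """Keep, per 30-min slot, the fix nearest the slot time within tolerance.

    Positions are never interpolated — fabricated positions would corrupt
    the speed-based flight classification. Slots with no fix within
    tolerance are gaps (absent rows).
    """
    out = []
    for ind, g in _per_individual(df):
        g = g.reset_index(drop=True)
        slots = g["timestamp"].dt.round("30min")
        offset = (g["timestamp"] - slots).abs()
        ok = offset <= pd.Timedelta(minutes=tolerance_min)
        g = g[ok].assign(slot=slots[ok], _off=offset[ok])
        g = (g.sort_values(["slot", "_off"]).drop_duplicates("slot", keep="first")
             .drop(columns="_off").sort_values("slot"))
        out.append(g)
    res = pd.concat(out, ignore_index=True) if out else df.iloc[0:0]
    return res.reset_index(drop=True)


def ground_speed_kmh(lon1, lat1, t1, lon2, lat2, t2):
    """Great-circle distance over elapsed time; NaN for zero elapsed time."""
    dt_h = (pd.Timestamp(t2) - pd.Timestamp(t1)).total_seconds() / 3600.0
    if dt_h <= 0:
        return np.nan
    return float(haversine_km(lon1, lat1, lon2, lat2)) / dt_h


def add_step_metrics(df: pd.DataFrame) -> pd.DataFrame:
    """Add step speed (km/h) and bearing of the step ending at each fix."""
    df = df.copy()
    df["step_kmh"] = np.nan
    df["bearing"] = np.nan
    for ind, g in _per_individual(df):
        idx = g.index
        lon, lat = g["lon"].to_numpy(), g["lat"].to_numpy()
        t = g["timestamp"].astype("int64").to_numpy() / 1e9
        if len(g) < 2:
            continue
        dt_h = np.diff(t) / 3600.0
        dist = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        with np.errstate(divide="ignore", invalid="ignore"):
            spd = dist / dt_h
        brg = initial_bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg[dist < 1e-9] = np.nan  # zero-length step: direction undefined
        df.loc[idx[1:], "step_kmh"] = spd
        df.loc[idx[1:], "bearing"] = brg
    return df


def classify_flight(df: pd.DataFrame, threshold_kmh: float = FLIGHT_SPEED_KMH,
                    slot_minutes: int = 30) -> pd.DataFrame:
    """Flag 30-min intervals as migratory flight.

    An interval (fix i -> fix i+1, consecutive slots) is a flight iff the
    instantaneous ground speed exceeds ``threshold_kmh`` at BOTH endpoints
    (strict inequality). Endpoint speed is the device-reported instantaneous
    speed when available, else the speed of the step ending at the fix.
    ``flight`` is stored on the interval's starting fix.
    """
    df = df.copy()
    if "instant_speed_kmh" in df.columns and df["instant_speed_kmh"].notna().any():
        endpoint = pd.to_numeric(df["instant_speed_kmh"], errors="coerce")
    else:
        if "step_kmh" not in df.columns:
            df = add_step_metrics(df)
        endpoint = df["step_kmh"]
    df["_endpoint_kmh"] = endpoint
    df["flight"] = False
    for ind, g in _per_individual(df):
        idx = g.index
        if len(g) < 2:
            continue
        tkey = g["slot"] if "slot" in g.columns else g["timestamp"]
        gap_ok = tkey.diff().iloc[1:] == pd.Timedelta(minutes=slot_minutes)
        v = g["_endpoint_kmh"].to_numpy()
        fl = (v[:-1] > threshold_kmh) & (v[1:] > threshold_kmh) & gap_ok.to_numpy()
        df.loc[idx[:-1], "flight"] = fl
    df["in_flight_fix"] = False
    for ind, g in _per_individual(df):
        idx = g.index
        fl = g["flight"].to_numpy()
        part = fl.copy()
        part[1:] |= fl[:-1]
        df.loc[idx, "in_flight_fix"] = part
    return df.drop(columns="_endpoint_kmh")


def annotate_solar(df: pd.DataFrame) -> pd.DataFrame:
    """Add solar phase per fix and daylight/dark hours of the fix's UTC date."""
    df = df.copy()
    phases = np.empty(len(df), dtype=object)
    dayl = np.empty(len(df))
    dark = np.empty(len(df))
    cache = {}
    lons = df["lon"].to_numpy()
    lats = df["lat"].to_numpy()
    times = df["timestamp"].dt.tz_convert("UTC")
    for i, (lon, lat, ts) in enumerate(zip(lons, lats, times)):
        phases[i] = solar.solar_phase(lon, lat, ts.to_pydatetime())
        key = (round(lon, 1), round(lat, 1), ts.date())
        if key not in cache:
            cache[key] = solar.daylight_hours(lon, lat, ts.date())
        dayl[i], dark[i] = cache[key]
    df["phase"] = phases
    df["daylight_h"] = dayl
    df["dark_h"] = dark
    return df


def process_tracks(df: pd.DataFrame, max_speed_kmh: float = 150.0,
                   max_climb_ms: float = 20.0,
                   tolerance_min: float = 5.0) -> pd.DataFrame:
    """Full preprocessing chain: filter -> resample -> steps -> flight -> solar."""
    df = quality_filter(df, max_speed_kmh, max_climb_ms)
    df = resample_30min(df, tolerance_min)
    df = add_step_metrics(df)
    df = classify_flight(df)
    return annotate_solar(df)
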