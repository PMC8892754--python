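"""Environmental annotation: pressure-level weather, wind support, water overlap.

Weather grids are xarray Datasets on a regular lon/lat grid at 6-h synoptic
times and the eight standard pressure levels (1000 ... 300 mb). A fix is
matched to the pressure level nearest its GPS altitude via the ISA
barometric formula, then the field is interpolated bilinearly in space.
Wind (u, v) is additionally interpolated linearly in time; other variables
are joined only at fixes falling exactly on the synoptic hours.

Wind support follows the tailwind-assistance decomposition fa = y cos(theta)
where y is wind speed and theta the angle between the track direction and
the direction the wind blows toward; crosswind = y sin(theta), positive when
the wind comes from the bird's left.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr
from shapely import contains_xy
from shapely.geometry import LineString, Point

from .geo import aeq_project
from .raster import Raster
from .segmentation import TravelingSegment
from .synthetic import AQUATIC_CODES, PRESSURE_LEVELS_MB

WIND_VARS = ("u_wind", "v_wind")
LEVEL_VARS = ("u_wind", "v_wind", "air_temperature", "vertical_flow")

# ISA constants
_P0 = 1013.25   # hPa
_T0 = 288.15    # K
_LAPSE = 0.0065  # K/m
_EXP = 5.25588


def pressure_from_altitude_hpa(altitude_m) -> np.ndarray:
    """International Standard Atmosphere pressure at a geometric altitude.

    Altitudes are clamped to [-500 m, 16 km] (beyond which the troposphere
    formula and the listed levels stop being meaningful).
    """
    h = np.clip(np.asarray(altitude_m, dtype=float), -500.0, 16000.0)
    return _P0 * (1.0 - _LAPSE * h / _T0) ** _EXP


def nearest_pressure_level(altitude_m) -> np.ndarray:
    """Nearest of the eight standard levels to the ISA pressure at altitude."""
    p = np.atleast_1d(pressure_from_altitude_hpa(altitude_m))
    levels = np.asarray(PRESSURE_LEVELS_MB, dtype=float)
    idx = np.argmin(np.abs(p[:, None] - levels[None, :]), axis=1)
    out = levels[idx]
    return out if np.asarray(altitude_m).ndim else float(out[0])


def interpolate_field(ds: xr.Dataset, var: str, lon: float, lat: float,
                      time, level: float | None = None,
                      time_interp: bool = False) -> float:
    """Bilinear spatial interpolation of one variable at a point.

    With ``time_interp`` the value is additionally linear in time between
    the bracketing 6-h steps (the wind convention); otherwise ``time`` must
    fall exactly on a grid time (the synoptic-hour convention for all other
    variables) or NaN is returned.
    """
    da = ds[var]
    t = pd.Timestamp(time)
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    if "level" in da.dims:
        if level is None:
            raise ValueError(f"{var} is a pressure-level variable; level required")
        da = da.sel(level=float(level))
    lon_min, lon_max = float(da.lon.min()), float(da.lon.max())
    lat_min, lat_max = float(da.lat.min()), float(da.lat.max())
    if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
        return np.nan
    if time_interp:
        tmin, tmax = pd.Timestamp(da.time.values.min()), pd.Timestamp(da.time.values.max())
        if not (tmin <= t <= tmax):
            return np.nan
        val = da.interp(time=np.datetime64(t), lon=lon, lat=lat, method="linear")
    else:
        times = pd.DatetimeIndex(da.time.values)
        if t not in times:
            return np.nan
        val = da.sel(time=np.datetime64(t)).interp(lon=lon, lat=lat, method="linear")
    return float(val)


def tailwind_crosswind(bearing_deg, u, v, signed_crosswind: bool = True):
    """Decompose wind (u east, v north, m/s) along/across a track bearing.

    Returns ``(tailwind, crosswind, wind_speed, theta_deg)``. theta is the
    circular difference between the track bearing and the compass direction
    the wind blows TOWARD, so tailwind is positive when the wind supports
    the movement. Crosswind is positive for wind from the bird's left; pass
    ``signed_crosswind=False`` for magnitude only.
    """
    bearing = np.radians(np.asarray(bearing_deg, dtype=float))
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    y = np.hypot(u, v)
    wind_to = np.arctan2(u, v)          # compass radians
    theta = wind_to - bearing
    fa = y * np.cos(theta)
    cross = y * np.sin(theta)
    if not signed_crosswind:
        cross = np.abs(cross)
    return fa, cross, y, np.degrees(np.arctan2(np.sin(theta), np.cos(theta)))


def annotate_wind(fixes: pd.DataFrame, weather: xr.Dataset) -> pd.DataFrame:
    """Per-fix wind annotation for flight fixes with a defined step bearing.

    Adds u, v (time- and space-interpolated at the fix's nearest pressure
    level), tailwind_ms and crosswind_ms columns; non-flight or
    bearing-less fixes carry NaN.
    """
    fixes = fixes.copy()
    for c in ("u_ms", "v_ms", "tailwind_ms", "crosswind_ms"):
        fixes[c] = np.nan
    alt = pd.to_numeric(fixes.get("gps_altitude", 0.0), errors="coerce").fillna(0.0)
    levels = np.atleast_1d(nearest_pressure_level(alt.to_numpy()))
    flying = fixes.get("in_flight_fix", pd.Series(True, index=fixes.index)).astype(bool)
    # movement direction: the flight step the fix participates in — forward
    # step when the interval starting here is a flight, else the incoming step
    bearing = fixes.get("bearing", pd.Series(np.nan, index=fixes.index)).copy()
    if "flight" in fixes.columns:
        fwd = bearing.shift(-1)
        use_fwd = fixes["flight"].astype(bool) & fwd.notna()
        bearing[use_fwd] = fwd[use_fwd]
    fixes["bearing_used"] = bearing
    for i, (idx, row) in enumerate(fixes.iterrows()):
        if not flying.loc[idx] or pd.isna(bearing.loc[idx]):
            continue
        row = row.copy()
        row["bearing"] = bearing.loc[idx]
        u = interpolate_field(weather, "u_wind", row["lon"], row["lat"],
                              row["timestamp"], level=levels[i], time_interp=True)
        v = interpolate_field(weather, "v_wind", row["lon"], row["lat"],
                              row["timestamp"], level=levels[i], time_interp=True)
        if np.isnan(u) or np.isnan(v):
            continue
        fa, cross, _, _ = tailwind_crosswind(row["bearing"], u, v)
        fixes.loc[idx, ["u_ms", "v_ms", "tailwind_ms", "crosswind_ms"]] = \
            [u, v, float(fa), float(cross)]
    return fixes


def annotate_weather_synoptic(fixes: pd.DataFrame, weather: xr.Dataset) -> pd.DataFrame:
    """Join non-wind weather at fixes on the 00/06/12/18 UTC synoptic hours."""
    fixes = fixes.copy()
    cols = {"air_temperature": True, "vertical_flow": True,
            "surface_temperature": False, "precipitation": False,
            "cloud_cover": False}
    for c in cols:
        fixes[c] = np.nan
    alt = pd.to_numeric(fixes.get("gps_altitude", 0.0), errors="coerce").fillna(0.0)
    levels = np.atleast_1d(nearest_pressure_level(alt.to_numpy()))
    ts = fixes["timestamp"].dt.tz_convert("UTC")
    synoptic = (ts.dt.hour % 6 == 0) & (ts.dt.minute == 0)
    for i, (idx, row) in enumerate(fixes.iterrows()):
        if not synoptic.loc[idx]:
            continue
        for var, has_level in cols.items():
            fixes.loc[idx, var] = interpolate_field(
                weather, var, row["lon"], row["lat"], row["timestamp"],
                level=levels[i] if has_level else None, time_interp=False)
    return fixes


def water_overlap_segment(segment, landscape: Raster,
                          buffer_km: float = 5.0) -> float:
    """Aquatic-pixel proportion within a buffer_km corridor around a segment.

    The segment polyline is buffered ``buffer_km`` on each side in an
    azimuthal-equidistant projection centered on the segment, and the
    proportion is water pixels / all pixels whose centers fall inside the
    buffer. Direction-reversal invariant by construction.
    """
    fixes = segment.fixes if isinstance(segment, TravelingSegment) else segment
    lons = np.asarray(fixes["lon"], dtype=float)
    lats = np.asarray(fixes["lat"], dtype=float)
    if lons.size == 0:
        raise ValueError("empty segment")
    lon0, lat0 = float(np.mean(lons)), float(np.mean(lats))
    x, y = aeq_project(lons, lats, lon0, lat0)
    line = (LineString(np.column_stack([x, y])) if lons.size > 1
            else Point(x[0], y[0]))
    poly = line.buffer(buffer_km)

    pad = (buffer_km / 111.32) * 1.5 + landscape.cellsize
    sel_lon_min, sel_lon_max = lons.min() - pad, lons.max() + pad
    sel_lat_min, sel_lat_max = lats.min() - pad, lats.max() + pad
    if (sel_lon_min < landscape.west or sel_lon_max > landscape.east
            or sel_lat_min < landscape.south or sel_lat_max > landscape.north):
        raise ValueError("buffered segment extends outside the land-cover raster")
    c0 = max(int(landscape.col_of_lon(sel_lon_min)), 0)
    c1 = min(int(landscape.col_of_lon(sel_lon_max)) + 1, landscape.ncols)
    r0 = max(int(landscape.row_of_lat(sel_lat_max)), 0)
    r1 = min(int(landscape.row_of_lat(sel_lat_min)) + 1, landscape.nrows)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    plon = landscape.lon_of_col(cols)
    plat = landscape.lat_of_row(rows)
    glon, glat = np.meshgrid(plon, plat)
    px, py = aeq_project(glon.ravel(), glat.ravel(), lon0, lat0)
    inside = contains_xy(poly, px, py)
    if not inside.any():
        return np.nan
    codes = landscape.data[r0:r1, c0:c1].ravel()[inside]
    return float(np.isin(codes, AQUATIC_CODES).mean())


def elevation_at(dem: Raster, lon, lat):
    """Bilinear DEM elevation; nodata outside the raster."""
    return dem.sample_bilinear(lon, lat)


def annotate_segment(segment: TravelingSegment, landscape: Raster | None = None,
                     weather: xr.Dataset | None = None,
                     buffer_km: float = 5.0) -> dict:
    """Segment-level covariates: water overlap and mean weather annotations."""
    out: dict = {}
    if landscape is not None:
        out["water_overlap"] = water_overlap_segment(segment, landscape, buffer_km)
    if weather is not None:
        fx = annotate_wind(segment.fixes, weather)
        fx = annotate_weather_synoptic(fx, weather)
        for var in ("tailwind_ms", "crosswind_ms", "air_temperature",
                    "vertical_flow", "surface_temperature", "precipitation",
                    "cloud_cover"):
            out[var] = float(fx[var].mean()) if fx[var].notna().any() else np.nan
    return out
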