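"""Synthetic tracks, landscapes, DEMs and weather grids with known ground truth.

Every downstream stage of the pipeline (segmentation, behavior metrics,
annotation, habitat selection, mixed-model inference) is exercised against
data produced here, where the generating parameters — stopover schedule,
per-interval flight flags, daily distances, habitat effect sizes — are known
exactly and returned as a :class:`GroundTruth` record.

Land-cover rasters use the IGBP coding convention of the MODIS product the
pipeline consumes: 17 = water bodies, 11 = permanent wetlands (grouped as
aquatic habitat downstream), and a single non-water code (10, grasslands).
Weather grids mimic 6-hourly reanalysis fields on a 2.5 degree grid at the
eight standard pressure levels.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from . import solar
from .geo import destination, haversine_km
from .raster import M_PER_DEG, Raster, raster_from_meters

WATER_CODE = 17
WETLAND_CODE = 11
LAND_CODE = 10
AQUATIC_CODES = (WETLAND_CODE, WATER_CODE)

PRESSURE_LEVELS_MB = (1000, 925, 850, 700, 600, 500, 400, 300)

PATTERNS = ("uniform_random", "corridor", "patches",
            "homogeneous_water", "homogeneous_land")


# ---------------------------------------------------------------------------
# Landscapes and DEMs
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSpec:
    """Parameters of a synthetic categorical land-cover raster.

    resolution is meters per pixel (500 m mirrors the MODIS land-cover
    product); origin is the (lon, lat) of the south-west corner.
    ``wetland_share`` splits aquatic pixels between wetland (11) and open
    water (17). For the corridor pattern ``background_water`` scatters
    additional aquatic pixels outside the band.
    """
    seed: int = 0
    width: int = 400
    height: int = 400
    resolution: float = 500.0
    origin: tuple = (0.0, 0.0)
    water_fraction: float = 0.3
    pattern: str = "uniform_random"
    wetland_share: float = 0.2
    background_water: float = 0.0
    patch_scale: float = 10.0   # pixels; smoothing length of the patch field

    def validate(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("raster dimensions must be positive")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must be in [0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0.0 <= self.wetland_share <= 1.0:
            raise ValueError("wetland_share must be in [0, 1]")


def generate_landscape(spec: LandscapeSpec) -> Raster:
    """Categorical IGBP raster realizing ``spec``; reproducible from its seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    if spec.pattern == "homogeneous_water":
        water = np.ones((h, w), dtype=bool)
    elif spec.pattern == "homogeneous_land":
        water = np.zeros((h, w), dtype=bool)
    elif spec.pattern == "uniform_random":
        water = rng.random((h, w)) < spec.water_fraction
    elif spec.pattern == "corridor":
        band_px = int(round(spec.water_fraction * w))
        c0 = (w - band_px) // 2
        water = np.zeros((h, w), dtype=bool)
        water[:, c0:c0 + band_px] = True
        if spec.background_water > 0:
            bg = rng.random((h, w)) < spec.background_water
            bg[:, c0:c0 + band_px] = False
            water |= bg
    else:  # patches: thresholded smoothed noise at the exact quantile
        noise = rng.standard_normal((h, w))
        fld = gaussian_filter(noise, sigma=spec.patch_scale, mode="wrap")
        thr = np.quantile(fld, 1.0 - spec.water_fraction)
        water = fld >= thr
        if spec.water_fraction == 0.0:
            water[:] = False

    codes = np.full((h, w), LAND_CODE, dtype=np.int16)
    wet = rng.random((h, w)) < spec.wetland_share
    codes[water & wet] = WETLAND_CODE
    codes[water & ~wet] = WATER_CODE
    return raster_from_meters(codes, spec.origin[0], spec.origin[1], spec.resolution)


def generate_dem(seed: int, like: Raster, relief_m: float = 200.0,
                 base_m: float = 0.0, smooth_px: float = 15.0) -> Raster:
    """Smooth random terrain on the grid of ``like``; relief_m = 0 gives flat ground."""
    rng = np.random.default_rng(seed)
    if relief_m <= 0:
        data = np.full_like(like.data, base_m, dtype=float)
    else:
        fld = gaussian_filter(rng.standard_normal(like.data.shape),
                              sigma=smooth_px, mode="wrap")
        fld = (fld - fld.min()) / max(np.ptp(fld), 1e-12)
        data = base_m + relief_m * fld
    return Raster(data=data, west=like.west, north=like.north,
                  cellsize=like.cellsize, nodata=like.nodata)


def water_mask(landscape: Raster) -> np.ndarray:
    return np.isin(landscape.data, AQUATIC_CODES)


def _disc_water_proportion(landscape: Raster, lon: float, lat: float,
                           radius_km: float = 5.0) -> float:
    # local import to avoid a cycle; the selection module owns the public API
    from .selection import water_proportion_at
    return water_proportion_at(landscape, lon, lat, radius_km=radius_km)


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSpec:
    """Generative parameters of one synthetic migratory track.

    The bird flies a fixed compass heading. Days listed in
    ``stopover_schedule`` (start day index, duration in days; day 0 = first
    day) are stopovers with negligible net displacement. On travel days each
    30-min interval is a flight with probability ``flight_prob_day`` or
    ``flight_prob_night`` by solar phase, and the day's distance is

        cruise_speed * flight_hours + water_effect_speed * w + intercept + noise

    where w is the aquatic proportion within 5 km of the day's start — the
    ground-truth habitat effect recovered by the inference stage.
    """
    seed: int = 0
    individual_id: str = "bird1"
    n_days: int = 10
    sampling_interval: int = 30           # minutes; 30 is the native cadence
    start: tuple = (1.0, 1.0)             # lon, lat
    start_time: str = "2021-09-01T00:00:00"
    stopover_schedule: tuple = ()         # ((start_day, duration_days), ...)
    flight_prob_day: float = 0.8
    flight_prob_night: float = 0.4
    cruise_speed: float = 40.0            # km/h, must exceed the 10 km/h flight rule
    heading: float = 180.0                # degrees
    height_agl_mean: float = 300.0        # m
    height_agl_sd: float = 100.0
    water_effect_speed: float = 0.0       # km/day per unit water proportion
    random_intercept: float = 0.0         # km/day individual offset
    daily_noise_sd: float = 0.0           # km/day
    altitude_noise_sd: float = 0.0        # m, GPS altitude noise
    position_noise_km: float = 0.0        # isotropic GPS position noise
    gross_error_rate: float = 0.0         # per-fix chance of a +8000 m spike

    def validate(self):
        for p in (self.flight_prob_day, self.flight_prob_night):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flight probabilities must be in [0, 1]")
        if self.cruise_speed <= 10.0:
            raise ValueError("cruise_speed must exceed 10 km/h so that "
                             "traveling intervals classify as flight")
        if self.n_days < 1:
            raise ValueError("n_days must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, for round-trip tests downstream."""
    individual_id: str
    start_time: str
    heading: float
    beta_water: float
    stopover_days: list            # day indices
    flight_flags: list             # (n_days, 48) 0/1, native 30-min intervals
    interval_phase: list           # (n_days, 48) phase labels
    day_distance_km: list
    day_water: list
    day_flight_hours: list

    def travel_runs(self):
        """Maximal runs of consecutive travel days as (start, end) inclusive."""
        stop = set(self.stopover_days)
        runs, cur = [], None
        n = len(self.day_distance_km)
        for d in range(n):
            if d in stop:
                if cur is not None:
                    runs.append((cur, d - 1))
                    cur = None
            elif cur is None:
                cur = d
        if cur is not None:
            runs.append((cur, n - 1))
        return runs

    def segment_speed_kmday(self, run):
        d0, d1 = run
        return float(np.sum(self.day_distance_km[d0:d1 + 1]) / (d1 - d0 + 1))

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _phase_of(lon, lat, ts):
    return solar.solar_phase(lon, lat, ts)


def generate_track(tspec: TrackSpec, landscape: Raster | None = None,
                   dem: Raster | None = None):
    """Simulate one track; returns ``(fixes DataFrame, GroundTruth)``.

    The DataFrame columns are the package-internal tidy form:
    individual_id, timestamp (UTC), lon, lat, gps_altitude (m asl),
    instant_speed_kmh.
    """
    tspec.validate()
    rng = np.random.default_rng(tspec.seed)
    t0 = pd.Timestamp(tspec.start_time, tz="UTC")
    n_days = tspec.n_days
    ipd = 48  # native 30-min intervals per day

    stopover_days = set()
    for s, dur in tspec.stopover_schedule:
        stopover_days.update(range(s, s + dur))
    stopover_days = {d for d in stopover_days if 0 <= d < n_days}

    if landscape is not None:
        lon0, lat0 = tspec.start
        if not bool(landscape.contains(lon0, lat0)):
            raise ValueError("track start outside landscape extent")

    # node positions at every 30-min boundary: n_days*48 + 1 nodes
    node_lon = np.empty(n_days * ipd + 1)
    node_lat = np.empty(n_days * ipd + 1)
    node_lon[0], node_lat[0] = tspec.start
    step_km = np.zeros(n_days * ipd)          # km moved in each native interval
    flags = np.zeros((n_days, ipd), dtype=bool)
    phases = np.empty((n_days, ipd), dtype=object)
    day_distance = np.zeros(n_days)
    day_water = np.zeros(n_days)
    day_hours = np.zeros(n_days)

    for d in range(n_days):
        i0 = d * ipd
        pos = (node_lon[i0], node_lat[i0])
        if landscape is not None and not bool(landscape.contains(*pos)):
            raise ValueError(f"track leaves the landscape raster extent on day {d}")
        # phase of each interval midpoint, evaluated at the day-start position
        for j in range(ipd):
            mid = (t0 + pd.Timedelta(days=d, minutes=30 * j + 15)).to_pydatetime()
            phases[d, j] = _phase_of(pos[0], pos[1], mid)
        if d in stopover_days:
            node_lon[i0 + 1:i0 + ipd + 1] = pos[0]
            node_lat[i0 + 1:i0 + ipd + 1] = pos[1]
            continue
        p = np.where(np.char.equal(phases[d].astype(str), solar.DAY),
                     tspec.flight_prob_day,
                     np.where(np.char.equal(phases[d].astype(str), solar.NIGHT),
                              tspec.flight_prob_night,
                              0.5 * (tspec.flight_prob_day + tspec.flight_prob_night)))
        fl = rng.random(ipd) < p
        # The endpoint-speed flight rule cannot represent a single stationary
        # interval inside a flight bout (both endpoints still move), so the
        # generator never emits one: isolated pauses are closed, including
        # across the midnight boundary from the previous travel day.
        prev_last = d > 0 and d - 1 not in stopover_days and flags[d - 1, -1]
        if prev_last and not fl[0] and fl[1]:
            fl[0] = True
        fl[1:-1] |= fl[:-2] & fl[2:]
        if fl[-2] and not fl[-1]:
            fl[-1] = True
        nfl = int(fl.sum())
        if nfl == 0:  # force a minimal travel day so the segment rule holds
            fl[ipd // 2] = True
            nfl = 1
        flags[d] = fl
        hours = 0.5 * nfl
        w = 0.0
        if landscape is not None and not bool(
                np.all(landscape.data == LAND_CODE)):
            w = _disc_water_proportion(landscape, pos[0], pos[1])
        dist = (tspec.cruise_speed * hours + tspec.water_effect_speed * w
                + tspec.random_intercept)
        if tspec.daily_noise_sd > 0:
            dist += rng.normal(0.0, tspec.daily_noise_sd)
        dist = max(dist, 11.0 * 0.5 * nfl)    # keep per-interval speed > 10 km/h
        per_step = dist / nfl
        lon, lat = pos
        for j in range(ipd):
            if fl[j]:
                lon, lat = destination(lon, lat, tspec.heading, per_step)
                step_km[i0 + j] = per_step
            node_lon[i0 + j + 1] = lon
            node_lat[i0 + j + 1] = lat
        day_distance[d] = dist
        day_water[d] = w
        day_hours[d] = hours

    if landscape is not None:
        if not bool(np.all(landscape.contains(node_lon, node_lat))):
            raise ValueError("track leaves the landscape raster extent")

    # --- emit fixes at the requested cadence ------------------------------
    total_min = n_days * 24 * 60
    times_min = np.arange(0, total_min, tspec.sampling_interval)
    fix_lon = np.empty(times_min.size)
    fix_lat = np.empty(times_min.size)
    speeds = np.empty(times_min.size)
    iv_speed = step_km / 0.5  # km/h in each native interval
    for k, m in enumerate(times_min):
        idx = min(int(m // 30), n_days * ipd - 1)
        frac = (m - idx * 30) / 30.0
        if frac == 0.0 or step_km[idx] == 0.0:
            if frac == 0.0:
                fix_lon[k], fix_lat[k] = node_lon[idx], node_lat[idx]
            else:
                fix_lon[k], fix_lat[k] = node_lon[idx + 1], node_lat[idx + 1]
                # stationary interval: position already at the (unmoved) node
        else:
            fix_lon[k], fix_lat[k] = destination(
                node_lon[idx], node_lat[idx], tspec.heading, frac * step_km[idx])
        # instantaneous speed at the fix: movement in either adjacent interval
        before = iv_speed[idx - 1] if (frac == 0.0 and idx > 0) else (
            iv_speed[idx] if frac > 0 else 0.0)
        after = iv_speed[idx] if idx < iv_speed.size else 0.0
        speeds[k] = max(before, after)

    timestamps = t0 + pd.to_timedelta(times_min, unit="m")
    if dem is not None:
        ground = np.asarray(dem.sample_bilinear(fix_lon, fix_lat), dtype=float)
        ground = np.where(ground == dem.nodata, 0.0, ground)
    else:
        ground = np.zeros(times_min.size)
    flying = speeds > 10.0
    agl = np.where(flying,
                   np.maximum(rng.normal(tspec.height_agl_mean,
                                         tspec.height_agl_sd, times_min.size), 5.0),
                   rng.uniform(0.0, 2.0, times_min.size))
    alt = ground + agl
    if tspec.altitude_noise_sd > 0:
        alt = alt + rng.normal(0.0, tspec.altitude_noise_sd, times_min.size)
    if tspec.gross_error_rate > 0:
        spikes = rng.random(times_min.size) < tspec.gross_error_rate
        alt = np.where(spikes, alt + 8000.0, alt)
    if tspec.position_noise_km > 0:
        bear = rng.uniform(0.0, 360.0, times_min.size)
        rad = np.abs(rng.normal(0.0, tspec.position_noise_km, times_min.size))
        fix_lon, fix_lat = destination(fix_lon, fix_lat, bear, rad)

    fixes = pd.DataFrame({
        "individual_id": tspec.individual_id,
        "timestamp": timestamps,
        "lon": fix_lon,
        "lat": fix_lat,
        "gps_altitude": alt,
        "instant_speed_kmh": speeds,
    })
    truth = GroundTruth(
        individual_id=tspec.individual_id,
        start_time=str(t0),
        heading=tspec.heading,
        beta_water=tspec.water_effect_speed,
        stopover_days=sorted(stopover_days),
        flight_flags=flags.astype(int).tolist(),
        interval_phase=phases.tolist(),
        day_distance_km=day_distance.tolist(),
        day_water=day_water.tolist(),
        day_flight_hours=day_hours.tolist(),
    )
    return fixes, truth


def simulate_behavior_table(seed: int = 0, n_individuals: int = 20,
                            n_segments: int = 10, beta_water: float = -200.0,
                            intercept: float = 400.0, sd_individual: float = 30.0,
                            sd_noise: float = 50.0,
                            n_noise_predictors: int = 2) -> pd.DataFrame:
    """Segment-level behavior table from a known mixed-effects truth.

    One row per traveling segment: a water-overlap covariate uniform on
    [0, 1], ``n_noise_predictors`` standard-normal covariates with zero true
    effect, a Gaussian individual random intercept (sd ``sd_individual``)
    and residual noise (sd ``sd_noise``):

        travel_speed = intercept + beta_water * water + b_ind + eps

    The direct data-level counterpart of a full track simulation, used for
    coefficient-recovery and coverage checks of the inference stage.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        b0 = rng.normal(0.0, sd_individual)
        for s in range(n_segments):
            w = rng.random()
            row = {"individual": f"ind{i:03d}", "segment": f"ind{i:03d}_s{s}",
                   "water": w,
                   "travel_speed": intercept + beta_water * w + b0
                   + rng.normal(0.0, sd_noise)}
            for j in range(n_noise_predictors):
                row[f"noise{j + 1}"] = rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


def corridor_benchmark(seed: int = 0, n_points: int = 60,
                       resolution_m: float = 500.0):
    """Benchmark scene for habitat-selection power and buffer-radius effects.

    A ~480 x 200 km landscape holding: a narrow (4 km) fully-aquatic
    corridor; a 30 km wide 'sea' whose near edge lies 45 km from the
    corridor center (reachable by 50 and 80 km availability buffers but not
    by 35 km); and ~3% scattered background water. Total aquatic fraction is
    ~10%. Returns ``(landscape, lons, lats)`` where the points run along the
    corridor center.

    Relocations on the corridor sit in locally rich habitat, so the
    randomization test has high power at 35 km. Larger buffers draw null
    points from the sea as well, so observed relocations lose rank and the
    significant fraction declines as the radius grows — the availability
    sample, not the use, changes with the radius.
    """
    rng = np.random.default_rng(seed)
    cell_km = resolution_m / 1000.0
    ncols = int(480 / cell_km)
    nrows = int(200 / cell_km)
    water = rng.random((nrows, ncols)) < 0.03
    corridor_km = (238.0, 242.0)
    sea_km = (285.0, 315.0)
    cols_km = (np.arange(ncols) + 0.5) * cell_km
    water[:, (cols_km >= corridor_km[0]) & (cols_km < corridor_km[1])] = True
    water[:, (cols_km >= sea_km[0]) & (cols_km < sea_km[1])] = True
    codes = np.where(water, WATER_CODE, LAND_CODE).astype(np.int16)
    landscape = raster_from_meters(codes, 0.0, 0.0, resolution_m)
    # points along the corridor center, at least 85 km from every edge
    center_lon = landscape.west + 240.0 / M_PER_DEG * 1000.0
    lat0 = landscape.south + 85.0 / M_PER_DEG * 1000.0
    lat1 = landscape.north - 85.0 / M_PER_DEG * 1000.0
    lats = np.linspace(lat0, lat1, n_points)
    lons = np.full(n_points, center_lon)
    return landscape, lons, lats


# ---------------------------------------------------------------------------
# Weather grids
# ---------------------------------------------------------------------------

def generate_weather_grid(seed: int, extent, start_time, n_steps: int = 8,
                          scenario: str = "zero_wind", u: float = 0.0,
                          v: float = 0.0, rotation_period_h: float = 24.0,
                          grid_deg: float = 2.5) -> xr.Dataset:
    """6-hourly pressure-level weather fields over ``extent`` = (w, s, e, n).

    Scenarios: ``zero_wind``; ``constant_wind`` (uniform u, v everywhere);
    ``rotating_wind`` (spatially uniform wind vector rotating with the given
    period — linear-in-time interpolation checks have a closed form).
    Non-wind fields (air/surface temperature, precipitation, cloud cover,
    vertical flow) are smooth seeded fields.
    """
    if scenario not in ("zero_wind", "constant_wind", "rotating_wind"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    w0, s0, e0, n0 = extent
    lon = np.arange(np.floor(w0 / grid_deg) * grid_deg,
                    np.ceil(e0 / grid_deg) * grid_deg + grid_deg / 2, grid_deg)
    lat = np.arange(np.floor(s0 / grid_deg) * grid_deg,
                    np.ceil(n0 / grid_deg) * grid_deg + grid_deg / 2, grid_deg)
    t0 = pd.Timestamp(start_time)
    if t0.tz is not None:
        t0 = t0.tz_convert("UTC").tz_localize(None)
    # snap to the previous synoptic hour so tracks fall inside the time hull
    t0 = t0.floor("6h")
    times = pd.date_range(t0, periods=n_steps, freq="6h")
    lev = np.array(PRESSURE_LEVELS_MB, dtype=float)

    shape4 = (times.size, lev.size, lat.size, lon.size)
    if scenario == "zero_wind":
        uu = np.zeros(shape4)
        vv = np.zeros(shape4)
    elif scenario == "constant_wind":
        uu = np.full(shape4, float(u))
        vv = np.full(shape4, float(v))
    else:
        mag = float(np.hypot(u, v)) or 10.0
        hours = (times - times[0]).total_seconds().to_numpy() / 3600.0
        ang = 2.0 * np.pi * hours / rotation_period_h
        uu = (mag * np.cos(ang))[:, None, None, None] * np.ones(shape4)
        vv = (mag * np.sin(ang))[:, None, None, None] * np.ones(shape4)

    # ISA-flavored temperature profile + smooth seeded anomalies
    level_height_km = 44.3308 * (1.0 - (lev / 1013.25) ** 0.190263)
    t_air = (288.15 - 6.5 * level_height_km)[None, :, None, None] * np.ones(shape4)
    t_air += gaussian_filter(rng.standard_normal(shape4), sigma=1.0) * 2.0
    omega = gaussian_filter(rng.standard_normal(shape4), sigma=1.0) * 0.05

    shape3 = (times.size, lat.size, lon.size)
    t_sfc = 288.15 + gaussian_filter(rng.standard_normal(shape3), sigma=1.0) * 3.0
    precip = np.clip(gaussian_filter(rng.standard_normal(shape3), sigma=1.0), 0, None) * 2.0
    cloud = np.clip(0.5 + gaussian_filter(rng.standard_normal(shape3), sigma=1.0) * 0.3,
                    0.0, 1.0)

    ds = xr.Dataset(
        {
            "u_wind": (("time", "level", "lat", "lon"), uu),
            "v_wind": (("time", "level", "lat", "lon"), vv),
            "air_temperature": (("time", "level", "lat", "lon"), t_air),
            "vertical_flow": (("time", "level", "lat", "lon"), omega),
            "surface_temperature": (("time", "lat", "lon"), t_sfc),
            "precipitation": (("time", "lat", "lon"), precip),
            "cloud_cover": (("time", "lat", "lon"), cloud),
        },
        coords={"time": times, "level": lev, "lat": lat, "lon": lon},
        attrs={"scenario": scenario},
    )
    return ds


def write_weather_netcdf(ds: xr.Dataset, path):
    """NETCDF3 via the scipy engine (no compiled netCDF dependency needed)."""
    ds.to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# Movebank-style CSV
# ---------------------------------------------------------------------------

MOVEBANK_COLUMNS = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "gps_altitude": "height-above-msl",
    "instant_speed_kmh": "ground-speed",   # written in m/s per Movebank convention
}


def write_movebank_csv(fixes: pd.DataFrame, path):
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S.000")
    out["instant_speed_kmh"] = out["instant_speed_kmh"] / 3.6  # -> m/s
    out = out.rename(columns=MOVEBANK_COLUMNS)
    out.to_csv(path, index=False)
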