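"""Minimal georeferenced raster container with ESRI ASCII-grid text I/O.

Grids are regular in geographic coordinates (WGS84 lon/lat degrees), row 0 at
the northern edge, pixel-center registration for sampling. Covers the two
raster roles in this package: categorical land cover (IGBP codes) and DEMs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: meters per degree of latitude (and of longitude at the equator)
M_PER_DEG = 111_320.0


@dataclass
class Raster:
    data: np.ndarray          # (nrows, ncols); row 0 = north
    west: float               # west edge, degrees lon
    north: float              # north edge, degrees lat
    cellsize: float           # degrees per pixel (square in degrees)
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cellsize

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    # -- coordinate helpers (pixel centers) --------------------------------
    def lon_of_col(self, col):
        return self.west + (np.asarray(col) + 0.5) * self.cellsize

    def lat_of_row(self, row):
        return self.north - (np.asarray(row) + 0.5) * self.cellsize

    def col_of_lon(self, lon):
        return np.floor((np.asarray(lon) - self.west) / self.cellsize).astype(int)

    def row_of_lat(self, lat):
        return np.floor((self.north - np.asarray(lat)) / self.cellsize).astype(int)

    def contains(self, lon, lat):
        return ((np.asarray(lon) >= self.west) & (np.asarray(lon) < self.east)
                & (np.asarray(lat) > self.south) & (np.asarray(lat) <= self.north))

    # -- sampling ----------------------------------------------------------
    def sample_nearest(self, lon, lat):
        """Value of the pixel containing each point; nodata outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        col = np.clip(self.col_of_lon(lon), 0, self.ncols - 1)
        row = np.clip(self.row_of_lat(lat), 0, self.nrows - 1)
        out = self.data[row, col].astype(float)
        return np.where(inside, out, self.nodata)

    def sample_bilinear(self, lon, lat):
        """Bilinear interpolation between the four surrounding pixel centers.

        Points outside the pixel-center hull are clamped to the edge row/col
        (equivalent to nearest-edge extension); points outside the raster
        bounds return nodata.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.contains(lon, lat)
        fx = (lon - self.west) / self.cellsize - 0.5
        fy = (self.north - lat) / self.cellsize - 0.5
        x0 = np.clip(np.floor(fx).astype(int), 0, self.ncols - 2)
        y0 = np.clip(np.floor(fy).astype(int), 0, self.nrows - 2)
        tx = np.clip(fx - x0, 0.0, 1.0)
        ty = np.clip(fy - y0, 0.0, 1.0)
        d = self.data.astype(float)
        v = (d[y0, x0] * (1 - tx) * (1 - ty) + d[y0, x0 + 1] * tx * (1 - ty)
             + d[y0 + 1, x0] * (1 - tx) * ty + d[y0 + 1, x0 + 1] * tx * ty)
        return np.where(inside, v, self.nodata)

    # -- text I/O (ESRI ASCII grid) ---------------------------------------
    def write_ascii(self, path):
        path = Path(path)
        hdr = (f"ncols {self.ncols}\nnrows {self.nrows}\n"
               f"xllcorner {self.west!r}\nyllcorner {self.south!r}\n"
               f"cellsize {self.cellsize!r}\nNODATA_value {self.nodata!r}\n")
        with open(path, "w") as fh:
            fh.write(hdr)
            np.savetxt(fh, self.data, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        header = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        nrows = int(header["nrows"])
        cell = header["cellsize"]
        return cls(data=data, west=header["xllcorner"],
                   north=header["yllcorner"] + nrows * cell,
                   cellsize=cell, nodata=header.get("nodata_value", -9999.0))


def raster_from_meters(data: np.ndarray, origin_lon: float, origin_lat: float,
                       resolution_m: float) -> Raster:
    """Wrap an array as a Raster whose pixel size is given in meters.

    The cell size is converted at ``M_PER_DEG`` (meters per degree of
    latitude); origin is the south-west corner.
    """
    cell = resolution_m / M_PER_DEG
    return Raster(data=data, west=origin_lon,
                  north=origin_lat + data.shape[0] * cell, cellsize=cell)
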