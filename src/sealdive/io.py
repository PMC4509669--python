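"""Readers and writers for every external format the pipeline touches.

Tables travel as pandas DataFrames with documented column schemas; rasters as
:class:`RasterGrid` backed by plain-text ESRI ASCII grids.  All timestamps are
normalized to UTC at read time (the input timezone is declared in the config,
so diel binning downstream is unambiguous).  CSV dialect is comma-separated,
'.' decimal, ISO-8601 times; a config switch accepts the ';' dialect.

Column schemas
--------------
argos      : animal_id, time, lon, lat, loc_class   (loc_class in {3,2,1,0,A,B})
dives      : animal_id, start, duration_s, max_depth_m, t1..t4 (s offsets), d1..d4 (m)
summaries  : animal_id, period_start, avg_depth_m, avg_duration_s, n_dives,
             time_diving_s, surface_time_s           (period_start at 00/06/12/18 UTC)
casts      : cast_id, animal_id, time, lon, lat, depth_m, temp_c, sal_psu (long format)
wind       : time, u, v                              (m/s, blowing-toward components)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

log = logging.getLogger(__name__)

LOC_CLASSES = ("3", "2", "1", "0", "A", "B")

#: Sea-ice concentration categories, encoded 1-6:
#: 1 open water (0/10-1/10), 2 very open drift ice (1/10-4/10),
#: 3 open drift ice (4/10-7/10), 4 close drift ice (7/10-9/10),
#: 5 very close drift ice (9/10-10/10), 6 land-fast ice.
ICE_CATEGORIES = {
    1: "open water",
    2: "very open drift ice",
    3: "open drift ice",
    4: "close drift ice",
    5: "very close drift ice",
    6: "land fast ice",
}


@dataclass
class PipelineConfig:
    """Run-wide configuration shared by ingest and downstream stages."""

    input_timezone: str = "UTC"
    csv_delimiter: str = ","
    wind_point_lon: float = 12.0   # west of Prins Karls Forland
    wind_point_lat: float = 78.5
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extra=raw)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required, what: str):
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing required column '{col}'")


def _read_csv(path, cfg: PipelineConfig | None):
    cfg = cfg or PipelineConfig()
    return pd.read_csv(path, sep=cfg.csv_delimiter)


def _to_utc(series: pd.Series, cfg: PipelineConfig | None) -> pd.Series:
    tz = (cfg or PipelineConfig()).input_timezone
    ts = pd.to_datetime(series, format="ISO8601")
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz)
    return ts.dt.tz_convert("UTC")


def read_argos(path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Read an Argos location table.

    Unknown location classes are rejected; exact duplicate rows (same animal,
    time and coordinates) are dropped with a logged count; output is sorted by
    (animal_id, time).
    """
    df = _read_csv(path, cfg)
    _require_columns(df, ["animal_id", "time", "lon", "lat", "loc_class"], "argos table")
    df = df.copy()
    df["loc_class"] = df["loc_class"].astype(str).str.strip()
    bad = sorted(set(df["loc_class"]) - set(LOC_CLASSES))
    if bad:
        raise FormatError(f"argos table: unknown location class(es) {bad}")
    df["time"] = _to_utc(df["time"], cfg)
    if not df["lat"].between(-90, 90).all():
        raise FormatError("argos table: latitude outside [-90, 90]")
    if not df["lon"].between(-180, 180).all():
        raise FormatError("argos table: longitude outside [-180, 180]")
    n0 = len(df)
    df = df.drop_duplicates(subset=["animal_id", "time", "lon", "lat"])
    if len(df) < n0:
        log.info("read_argos: dropped %d exact duplicate rows", n0 - len(df))
    return df.sort_values(["animal_id", "time"], kind="stable").reset_index(drop=True)


def write_argos(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


DIVE_PROFILE_COLS = ["t1", "t2", "t3", "t4", "d1", "d2", "d3", "d4"]


def read_dives(path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Read the transmitted-dive table (broken-stick profiles of 4 points)."""
    df = _read_csv(path, cfg)
    _require_columns(df, ["animal_id", "start", "duration_s", "max_depth_m"] + DIVE_PROFILE_COLS,
                     "dive table")
    df = df.copy()
    df["start"] = _to_utc(df["start"], cfg)
    if (df["duration_s"] < 8).any() or (df["max_depth_m"] < 6).any():
        raise DataError("dive table: dives must be >= 8 s and >= 6 m by definition")
    return df.sort_values(["animal_id", "start"], kind="stable").reset_index(drop=True)


def write_dives(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["start"] = out["start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_summaries(path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Read 6-hour dive summary records."""
    df = _read_csv(path, cfg)
    _require_columns(df, ["animal_id", "period_start", "avg_depth_m", "avg_duration_s",
                          "n_dives", "time_diving_s", "surface_time_s"], "summary table")
    df = df.copy()
    df["period_start"] = _to_utc(df["period_start"], cfg)
    if not df["period_start"].dt.hour.isin([0, 6, 12, 18]).all():
        raise FormatError("summary table: period_start must fall on 00/06/12/18 h")
    over = df["time_diving_s"] + df["surface_time_s"] > 21_600 + 1e-6
    if over.any():
        raise DataError("summary table: time_diving + surface_time exceeds 6 h")
    return df.sort_values(["animal_id", "period_start"], kind="stable").reset_index(drop=True)


def write_summaries(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["period_start"] = out["period_start"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_casts(path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Read CTD upcasts in long format; depths must be unique within a cast."""
    df = _read_csv(path, cfg)
    _require_columns(df, ["cast_id", "animal_id", "time", "lon", "lat",
                          "depth_m", "temp_c", "sal_psu"], "cast table")
    df = df.copy()
    df["time"] = _to_utc(df["time"], cfg)
    if not df["temp_c"].between(-2.5, 30).all():
        raise DataError("cast table: temperature outside [-2.5, 30] degC")
    if not df["sal_psu"].between(0, 41).all():
        raise DataError("cast table: salinity outside [0, 41] PSU")
    df = df.sort_values(["cast_id", "depth_m"], kind="stable").reset_index(drop=True)
    monotone = df.groupby("cast_id")["depth_m"].apply(lambda d: d.is_unique)
    if not monotone.all():
        raise DataError("cast table: duplicate depths within a cast")
    return df


def write_casts(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_wind(path, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Read a wind time series at a fixed grid point.

    The series must have a regular cadence; rows following a gap larger than
    the modal step are flagged in a boolean ``after_gap`` column rather than
    silently filled.
    """
    df = _read_csv(path, cfg)
    _require_columns(df, ["time", "u", "v"], "wind table")
    df = df.copy()
    df["time"] = _to_utc(df["time"], cfg)
    df = df.sort_values("time", kind="stable").reset_index(drop=True)
    steps = df["time"].diff().dropna()
    if len(steps):
        cadence = steps.mode().iloc[0]
        df["after_gap"] = df["time"].diff() > cadence
        df.loc[df.index[0], "after_gap"] = False
        n_gaps = int(df["after_gap"].sum())
        if n_gaps:
            log.warning("read_wind: %d cadence gaps flagged", n_gaps)
    else:
        df["after_gap"] = False
    return df


def write_wind(df: pd.DataFrame, path) -> None:
    out = df[["time", "u", "v"]].copy()
    out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

class OutsideDomain:
    """Typed sentinel returned for lookups outside a raster's bounds."""

    def __repr__(self):  # pragma: no cover
        return "OUTSIDE_DOMAIN"

    def __bool__(self):
        return False


OUTSIDE_DOMAIN = OutsideDomain()


@dataclass
class RasterGrid:
    """A single-band georeferenced grid with square cells.

    ``values[0, 0]`` is the north-west cell; ``x_ll``/``y_ll`` are the
    lower-left corner coordinates and ``cellsize`` the cell edge, all in the
    CRS units (decimal degrees for EPSG:4326).
    """

    values: np.ndarray
    x_ll: float
    y_ll: float
    cellsize: float
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("raster values must be 2-D")
        if not (self.cellsize > 0 and np.isfinite(self.cellsize)):
            raise FormatError("raster transform is not invertible (cellsize <= 0)")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self):
        """(x_min, y_min, x_max, y_max)."""
        return (self.x_ll, self.y_ll,
                self.x_ll + self.ncols * self.cellsize,
                self.y_ll + self.nrows * self.cellsize)

    def index(self, x, y):
        """(row, col) of the cell containing the point, or None if outside."""
        col = int(np.floor((x - self.x_ll) / self.cellsize))
        row = int(np.floor((self.y_ll + self.nrows * self.cellsize - y) / self.cellsize))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def lookup(self, x, y):
        """Value of the containing cell; OUTSIDE_DOMAIN beyond the bounds."""
        idx = self.index(x, y)
        if idx is None:
            return OUTSIDE_DOMAIN
        return self.values[idx]

    def lookup_many(self, x, y):
        """Vectorized lookup; returns (values, inside_mask).

        Outside points get NaN in ``values`` and False in the mask.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_ll) / self.cellsize).astype(int)
        row = np.floor((self.y_ll + self.nrows * self.cellsize - y) / self.cellsize).astype(int)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        return out, inside


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"raster: missing header field '{key}'")
    if header["cellsize"] <= 0:
        raise FormatError("raster transform is not invertible (cellsize <= 0)")
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError("raster: data shape does not match header")
    return RasterGrid(values=values, x_ll=header["xllcorner"], y_ll=header["yllcorner"],
                      cellsize=header["cellsize"],
                      nodata=header.get("nodata_value", -9999.0))


def write_raster(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x_ll:.10g}\n")
        fh.write(f"yllcorner {grid.y_ll:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        np.savetxt(fh, grid.values, fmt="%.9g")
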