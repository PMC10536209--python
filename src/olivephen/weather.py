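"""Daily temperature containers: site series, dormancy seasons, climatologies, grids.

All the phenology models in this package consume one of three shapes of
temperature data:

* a :class:`WeatherSeries` — a contiguous daily tmin/tmax(/tmean) record for
  one site (or grid cell), pandas-backed;
* a :class:`DormancySeason` — the 1 November (year Y−1) … 31 October (year Y)
  window of a series, the natural accounting year for dormancy-driven
  phenology in the northern hemisphere;
* a :class:`ClimatologySeries` — a 365-entry day-of-year mean year (Feb 29
  dropped) used for long-term spatial projection.

Gridded inputs (NetCDF, regular 0.1°-style lat/lon lattices) are wrapped in
:class:`TemperatureGrid` around an xarray Dataset.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    BoundsError,
    ContiguityError,
    FormatError,
    GridError,
    ValidationError,
    WindowError,
)

__all__ = [
    "WeatherSeries",
    "DormancySeason",
    "ClimatologySeries",
    "TemperatureGrid",
    "read_daily_weather",
    "write_daily_weather",
    "build_dormancy_season",
    "build_climatology",
    "load_temperature_grid",
    "extract_cell",
]

_REQUIRED_COLUMNS = ("tmin", "tmax")

# Day-of-year index of each (month, day) in a non-leap year; Feb 29 excluded.
_NOLEAP_DOY = {
    (d.month, d.day): i + 1
    for i, d in enumerate(pd.date_range("2001-01-01", "2001-12-31"))
}


def _validate_frame(frame: pd.DataFrame, *, context: str = "weather table") -> None:
    """Check contiguity and the tmin <= tmax (<= tmean bracketing) invariants."""
    if not isinstance(frame.index, pd.DatetimeIndex):
        raise FormatError(f"{context}: index must be dates")
    if len(frame) == 0:
        raise FormatError(f"{context}: empty table")
    deltas = np.diff(frame.index.values).astype("timedelta64[D]").astype(int)
    if np.any(deltas != 1):
        bad = int(np.argmax(deltas != 1))
        first_missing = (frame.index[bad] + pd.Timedelta(days=1)).date()
        raise ContiguityError(
            f"{context}: dates not contiguous; first missing day is {first_missing}"
        )
    invalid = frame["tmin"].to_numpy() > frame["tmax"].to_numpy()
    if invalid.any():
        row = int(np.argmax(invalid))
        raise ValidationError(
            f"{context}: tmin > tmax at row {row} ({frame.index[row].date()})"
        )
    if "tmean" in frame.columns:
        tm = frame["tmean"].to_numpy()
        out = (tm < frame["tmin"].to_numpy()) | (tm > frame["tmax"].to_numpy())
        if out.any():
            row = int(np.argmax(out))
            raise ValidationError(
                f"{context}: tmean outside [tmin, tmax] at row {row} "
                f"({frame.index[row].date()})"
            )


@dataclass
class WeatherSeries:
    """Contiguous daily temperature record for one site.

    ``frame`` has a DatetimeIndex and columns ``tmin``/``tmax`` and
    ``tmean`` (°C).  ``tmean_derived`` flags a mean that was filled in as
    (tmin+tmax)/2 rather than supplied.
    """

    site_id: str
    latitude: float
    longitude: float
    frame: pd.DataFrame
    tmean_derived: bool = False

    def __post_init__(self) -> None:
        frame = self.frame.sort_index()
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"weather table missing columns: {', '.join(missing)}")
        if "tmean" not in frame.columns:
            frame = frame.assign(tmean=(frame["tmin"] + frame["tmax"]) / 2.0)
            object.__setattr__(self, "tmean_derived", True)
        _validate_frame(frame, context=f"site {self.site_id}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def start(self) -> dt.date:
        return self.frame.index[0].date()

    @property
    def end(self) -> dt.date:
        return self.frame.index[-1].date()


@dataclass
class DormancySeason:
    """One phenology year of weather: 1 Nov of year Y−1 through 31 Oct of year Y.

    Phase dates are expressed as Julian days of the phenology year Y
    (Jan 1 = 1); days in Nov–Dec of Y−1 get non-positive values.
    """

    phenology_year: int
    frame: pd.DataFrame
    tmin: np.ndarray = field(init=False, repr=False)
    tmax: np.ndarray = field(init=False, repr=False)
    jdays: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        y = self.phenology_year
        first, last = self.frame.index[0], self.frame.index[-1]
        if first != pd.Timestamp(y - 1, 11, 1) or last != pd.Timestamp(y, 10, 31):
            raise WindowError(
                f"season for year {y} must span {y - 1}-11-01..{y}-10-31, "
                f"got {first.date()}..{last.date()}"
            )
        _validate_frame(self.frame, context=f"season {y}")
        self.tmin = self.frame["tmin"].to_numpy(dtype=float)
        self.tmax = self.frame["tmax"].to_numpy(dtype=float)
        origin = pd.Timestamp(y, 1, 1)
        self.jdays = (self.frame.index - origin).days.to_numpy() + 1

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def last_jday(self) -> int:
        """Julian day of 31 October — used as the failure penalty date."""
        return int(self.jdays[-1])


@dataclass
class ClimatologySeries:
    """Day-of-year mean year: 365 (tmin, tmax) entries, Feb 29 excluded."""

    frame: pd.DataFrame  # index: non-leap day-of-year 1..365; columns tmin, tmax
    source_years: tuple[int, int]
    site_id: str = "climatology"
    latitude: float = float("nan")
    longitude: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.frame) != 365 or list(self.frame.index) != list(range(1, 366)):
            raise ValidationError("climatology must have day-of-year index 1..365")
        if (self.frame["tmin"].to_numpy() > self.frame["tmax"].to_numpy()).any():
            raise ValidationError("climatology has tmin > tmax entries")

    def to_season(self, phenology_year: int = 2001) -> DormancySeason:
        """Wrap the mean year into a single Nov–Oct dormancy season.

        The default phenology year is non-leap so the season is exactly 365
        days and maps one-to-one onto the climatology entries.
        """
        y = phenology_year
        dates = pd.date_range(dt.date(y - 1, 11, 1), dt.date(y, 10, 31))
        keys = [(_NOLEAP_DOY[(d.month, d.day)] if (d.month, d.day) != (2, 29) else None)
                for d in dates]
        # A leap phenology year repeats Feb 28 for Feb 29.
        doys = [k if k is not None else _NOLEAP_DOY[(2, 28)] for k in keys]
        frame = pd.DataFrame(
            {
                "tmin": self.frame["tmin"].to_numpy()[np.asarray(doys) - 1],
                "tmax": self.frame["tmax"].to_numpy()[np.asarray(doys) - 1],
            },
            index=dates,
        )
        return DormancySeason(phenology_year=y, frame=frame)


def read_daily_weather(
    source,
    site_id: str = "site",
    latitude: float = float("nan"),
    longitude: float = float("nan"),
    kelvin: bool = False,
) -> WeatherSeries:
    """Read a ``date,tmin,tmax[,tmean]`` CSV into a validated WeatherSeries.

    Dates must be ISO-8601; rows are sorted by date on read.  ``kelvin=True``
    converts the temperature columns to °C.
    """
    frame = pd.read_csv(source)
    if "date" not in frame.columns:
        raise FormatError("weather table missing column: date")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"weather table missing columns: {', '.join(missing)}")
    try:
        idx = pd.DatetimeIndex(pd.to_datetime(frame["date"], format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable dates in weather table: {exc}") from exc
    cols = ["tmin", "tmax"] + (["tmean"] if "tmean" in frame.columns else [])
    data = frame[cols].astype(float).set_index(idx).sort_index()
    if kelvin:
        data[cols] = data[cols] - 273.15
    return WeatherSeries(
        site_id=site_id, latitude=latitude, longitude=longitude, frame=data
    )


def write_daily_weather(series: WeatherSeries, path: str | Path) -> None:
    """Write a WeatherSeries back to CSV at full float precision."""
    out = series.frame.copy()
    if series.tmean_derived:
        out = out.drop(columns="tmean")
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(path, index=False, float_format="%.17g")


def build_dormancy_season(series: WeatherSeries, phenology_year: int) -> DormancySeason:
    """Slice the Nov (Y−1) … Oct (Y) window out of a site series."""
    y = phenology_year
    start, end = pd.Timestamp(y - 1, 11, 1), pd.Timestamp(y, 10, 31)
    if series.frame.index[0] > start or series.frame.index[-1] < end:
        raise WindowError(
            f"series {series.site_id} ({series.start}..{series.end}) does not "
            f"cover the {y} season window {start.date()}..{end.date()}"
        )
    window = series.frame.loc[start:end, ["tmin", "tmax"]]
    return DormancySeason(phenology_year=y, frame=window)


def build_climatology(
    series: WeatherSeries, years: tuple[int, int]
) -> ClimatologySeries:
    """Day-of-year mean of tmin and tmax over an inclusive year range.

    Feb 29 values are dropped before averaging, so the result always has
    exactly 365 entries.
    """
    y0, y1 = years
    start, end = pd.Timestamp(y0, 1, 1), pd.Timestamp(y1, 12, 31)
    if series.frame.index[0] > start or series.frame.index[-1] < end:
        raise WindowError(
            f"series {series.site_id} does not cover calendar years {y0}..{y1}"
        )
    window = series.frame.loc[start:end]
    md = list(zip(window.index.month, window.index.day))
    keep = [pair != (2, 29) for pair in md]
    window = window.loc[keep]
    doy = np.array([_NOLEAP_DOY[pair] for pair in zip(window.index.month,
                                                      window.index.day)])
    grouped = window[["tmin", "tmax"]].groupby(doy).mean()
    grouped.index.name = "dayofyear"
    return ClimatologySeries(
        frame=grouped,
        source_years=(y0, y1),
        site_id=series.site_id,
        latitude=series.latitude,
        longitude=series.longitude,
    )


def _check_regular_axis(values: np.ndarray, name: str) -> None:
    if values.ndim != 1 or len(values) < 1:
        raise GridError(f"{name} axis must be 1-D and nonempty")
    if len(values) > 1:
        steps = np.diff(values)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise GridError(f"{name} axis must be strictly monotone")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise GridError(f"{name} axis step is irregular")


@dataclass
class TemperatureGrid:
    """Regular lat/lon lattice of temperature series.

    ``dataset`` holds ``tmin``/``tmax`` on dims ``(time, lat, lon)`` for
    daily grids or ``(dayofyear, lat, lon)`` for climatology grids.
    """

    dataset: xr.Dataset
    kind: str = "daily"  # "daily" | "climatology"

    def __post_init__(self) -> None:
        ds = self.dataset
        for var in _REQUIRED_COLUMNS:
            if var not in ds:
                raise GridError(f"grid is missing variable {var!r}")
        for axis in ("lat", "lon"):
            if axis not in ds.coords:
                raise GridError(f"grid is missing coordinate {axis!r}")
            _check_regular_axis(np.asarray(ds[axis].values, dtype=float), axis)
        if self.kind not in ("daily", "climatology"):
            raise GridError(f"unknown grid kind {self.kind!r}")
        if self.kind == "climatology" and ds.sizes.get("dayofyear") != 365:
            raise GridError("climatology grid must have a 365-entry dayofyear axis")

    @property
    def latitudes(self) -> np.ndarray:
        return np.asarray(self.dataset["lat"].values, dtype=float)

    @property
    def longitudes(self) -> np.ndarray:
        return np.asarray(self.dataset["lon"].values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.latitudes), len(self.longitudes)


def load_temperature_grid(
    source,
    tmin_var: str = "tmin",
    tmax_var: str = "tmax",
    lat_name: str = "lat",
    lon_name: str = "lon",
    time_name: str = "time",
    lat_window: tuple[float, float] | None = None,
    lon_window: tuple[float, float] | None = None,
    kelvin: bool = False,
) -> TemperatureGrid:
    """Load a (time, lat, lon) NetCDF temperature product.

    Variable/axis names are configurable; an optional lat/lon window subsets
    the grid on load.  A ``dayofyear`` time axis of length 365 is recognised
    as a climatology grid.
    """
    if isinstance(source, xr.Dataset):
        ds = source
    else:
        ds = xr.open_dataset(source, engine="scipy").load()
    rename = {}
    for old, new in ((tmin_var, "tmin"), (tmax_var, "tmax"),
                     (lat_name, "lat"), (lon_name, "lon")):
        if old != new:
            if old not in ds and old not in ds.coords:
                raise GridError(f"grid has no variable/axis named {old!r}")
            rename[old] = new
    if time_name != "time" and time_name in ds.dims and time_name != "dayofyear":
        rename[time_name] = "time"
    ds = ds.rename(rename)
    if kelvin:
        ds = ds.assign(tmin=ds["tmin"] - 273.15, tmax=ds["tmax"] - 273.15)
    if lat_window is not None:
        lo, hi = sorted(lat_window)
        ds = ds.sel(lat=(ds["lat"] >= lo) & (ds["lat"] <= hi))
    if lon_window is not None:
        lo, hi = sorted(lon_window)
        ds = ds.sel(lon=(ds["lon"] >= lo) & (ds["lon"] <= hi))
    kind = "climatology" if "dayofyear" in ds.dims else "daily"
    return TemperatureGrid(dataset=ds, kind=kind)


def _nearest_index(axis: np.ndarray, value: float, name: str) -> int:
    step = abs(axis[1] - axis[0]) if len(axis) > 1 else 0.0
    lo, hi = min(axis[0], axis[-1]), max(axis[0], axis[-1])
    if value < lo - step / 2 or value > hi + step / 2:
        raise BoundsError(f"{name}={value} outside grid bounds [{lo}, {hi}]")
    dist = np.abs(axis - value)
    # Ties (point equidistant between two centers) break toward lower index.
    return int(np.argmin(np.round(dist, 9)))


def extract_cell(
    grid: TemperatureGrid, latitude: float, longitude: float
) -> WeatherSeries | ClimatologySeries:
    """Pull the series of the grid cell whose center is nearest to a point."""
    i = _nearest_index(grid.latitudes, latitude, "latitude")
    j = _nearest_index(grid.longitudes, longitude, "longitude")
    cell = grid.dataset.isel(lat=i, lon=j)
    lat_c, lon_c = float(grid.latitudes[i]), float(grid.longitudes[j])
    site_id = f"cell_{lat_c:.3f}_{lon_c:.3f}"
    if grid.kind == "climatology":
        frame = pd.DataFrame(
            {"tmin": cell["tmin"].values, "tmax": cell["tmax"].values},
            index=pd.RangeIndex(1, 366),
        )
        frame.index.name = "dayofyear"
        years = tuple(cell.attrs.get("source_years", (0, 0)))
        return ClimatologySeries(
            frame=frame, source_years=years, site_id=site_id,
            latitude=lat_c, longitude=lon_c,
        )
    frame = pd.DataFrame(
        {"tmin": cell["tmin"].values, "tmax": cell["tmax"].values},
        index=pd.DatetimeIndex(cell["time"].values),
    )
    return WeatherSeries(
        site_id=site_id, latitude=lat_c, longitude=lon_c, frame=frame
    )
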