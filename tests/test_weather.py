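import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

import olivephen as op
from olivephen.errors import (
    BoundsError,
    ContiguityError,
    FormatError,
    GridError,
    ValidationError,
    WindowError,
)

from conftest import make_weather_frame


def csv(text):
    return io.StringIO(text)


class TestReadDailyWeather:
    def test_round_trip_is_exact(self, tmp_path):
        series = op.read_daily_weather(csv(
            "date,tmin,tmax\n"
            "1996-01-01,1.25,9.875\n"
            "1996-01-02,-0.333251953125,8.0\n"
            "1996-01-03,2.0,2.0\n"
        ), site_id="toy")
        assert len(series) == 3
        path = tmp_path / "w.csv"
        op.write_daily_weather(series, path)
        back = op.read_daily_weather(path, site_id="toy")
        pd.testing.assert_frame_equal(series.frame, back.frame)

    def test_rows_sorted_on_read(self):
        series = op.read_daily_weather(csv(
            "date,tmin,tmax\n1996-01-02,1,2\n1996-01-01,1,2\n"
        ))
        assert series.start == dt.date(1996, 1, 1)

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError, match="tmax"):
            op.read_daily_weather(csv("date,tmin\n1996-01-01,1\n"))

    def test_gap_names_first_missing_date(self):
        with pytest.raises(ContiguityError, match="1996-01-02"):
            op.read_daily_weather(csv(
                "date,tmin,tmax\n1996-01-01,1,2\n1996-01-03,1,2\n"
            ))

    def test_inverted_extremes_reports_row(self):
        with pytest.raises(ValidationError, match="row 1"):
            op.read_daily_weather(csv(
                "date,tmin,tmax\n1996-01-01,1,2\n1996-01-02,10,5\n"
            ))

    def test_supplied_tmean_outside_range_rejected(self):
        with pytest.raises(ValidationError, match="tmean"):
            op.read_daily_weather(csv(
                "date,tmin,tmax,tmean\n1996-01-01,1,2,5\n"
            ))

    def test_derived_tmean_flagged(self):
        series = op.read_daily_weather(csv("date,tmin,tmax\n1996-01-01,1,3\n"))
        assert series.tmean_derived
        assert series.frame["tmean"].iloc[0] == 2.0


class TestDormancySeason:
    def test_window_slice(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1996-01-01", 1096, 2, 8))
        season = op.build_dormancy_season(series, 1998)
        assert season.dates[0] == pd.Timestamp(1997, 11, 1)
        assert season.dates[-1] == pd.Timestamp(1998, 10, 31)

    @pytest.mark.parametrize("year,expected_len", [(1999, 365), (2000, 366)])
    def test_length_depends_on_leap_february(self, year, expected_len):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1995-01-01", 2557, 2, 8))
        assert len(op.build_dormancy_season(series, year)) == expected_len

    def test_missing_coverage_is_window_error(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1998-01-01", 365, 2, 8))
        with pytest.raises(WindowError):
            op.build_dormancy_season(series, 1998)

    def test_jdays_cross_new_year(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1996-01-01", 1096, 2, 8))
        season = op.build_dormancy_season(series, 1998)
        assert season.jdays[0] == -60  # 1 Nov of the previous year
        assert season.jdays[-1] == 304  # 31 Oct
        assert season.jdays[61] == 1  # 1 Jan


class TestClimatology:
    def test_mean_of_identical_years_is_either_year(self):
        frame = pd.concat([
            make_weather_frame("1996-01-01", 366, 2, 8),
            make_weather_frame("1997-01-01", 365, 2, 8),
        ])
        series = op.WeatherSeries("s", 40, 9, frame)
        clim = op.build_climatology(series, (1996, 1997))
        assert len(clim.frame) == 365
        assert (clim.frame["tmin"] == 2).all() and (clim.frame["tmax"] == 8).all()

    def test_arithmetic_mean_across_years(self):
        f1 = make_weather_frame("1997-01-01", 365, 0, 10)
        f2 = make_weather_frame("1998-01-01", 365, 2, 12)
        series = op.WeatherSeries("s", 40, 9, pd.concat([f1, f2]))
        clim = op.build_climatology(series, (1997, 1998))
        assert clim.frame.loc[1, "tmin"] == 1.0
        assert clim.frame.loc[1, "tmax"] == 11.0

    def test_leap_year_still_365_entries(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("2000-01-01", 366, 2, 8))
        clim = op.build_climatology(series, (2000, 2000))
        assert len(clim.frame) == 365

    def test_incomplete_coverage_is_window_error(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1997-06-01", 400, 2, 8))
        with pytest.raises(WindowError):
            op.build_climatology(series, (1997, 1998))

    def test_climatology_season_wraps_november_first(self):
        series = op.WeatherSeries("s", 40, 9, make_weather_frame("1997-01-01", 730, 2, 8))
        season = op.build_climatology(series, (1997, 1998)).to_season()
        assert len(season) == 365
        assert season.jdays[0] == -60


def toy_grid(lats=(40.0, 40.1), lons=(9.0, 9.1), n_time=365):
    import xarray as xr

    shape = (n_time, len(lats), len(lons))
    tmin = np.full(shape, 2.0) + np.arange(len(lats))[None, :, None]
    return xr.Dataset(
        {"tmin": (("time", "lat", "lon"), tmin),
         "tmax": (("time", "lat", "lon"), tmin + 6.0)},
        coords={"time": pd.date_range("2001-01-01", periods=n_time),
                "lat": list(lats), "lon": list(lons)},
    )


class TestTemperatureGrid:
    def test_netcdf_round_trip(self, tmp_path):
        path = tmp_path / "grid.nc"
        toy_grid().to_netcdf(path, engine="scipy")
        grid = op.load_temperature_grid(path)
        assert grid.shape == (2, 2)
        assert grid.kind == "daily"

    def test_irregular_axis_rejected(self):
        ds = toy_grid(lats=(40.0, 40.1, 40.3))
        with pytest.raises(GridError, match="irregular"):
            op.load_temperature_grid(ds)

    def test_longitude_window_subset(self):
        ds = toy_grid(lons=(9.0, 9.1, 9.2, 9.3))
        grid = op.load_temperature_grid(ds, lon_window=(9.05, 9.25))
        assert list(grid.longitudes) == [9.1, 9.2]

    def test_extract_exact_center(self):
        grid = op.load_temperature_grid(toy_grid())
        cell = op.extract_cell(grid, 40.1, 9.0)
        assert cell.frame["tmin"].iloc[0] == 3.0

    def test_equidistant_point_takes_lower_index(self):
        grid = op.load_temperature_grid(toy_grid())
        cell = op.extract_cell(grid, 40.05, 9.05)
        assert cell.frame["tmin"].iloc[0] == 2.0

    def test_every_center_maps_to_its_cell(self):
        grid = op.load_temperature_grid(toy_grid(lats=(40.0, 40.1, 40.2)))
        for i, lat in enumerate(grid.latitudes):
            for lon in grid.longitudes:
                cell = op.extract_cell(grid, float(lat), float(lon))
                assert cell.frame["tmin"].iloc[0] == 2.0 + i

    def test_outside_bounds_rejected(self):
        grid = op.load_temperature_grid(toy_grid())
        with pytest.raises(BoundsError):
            op.extract_cell(grid, 45.0, 9.0)
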