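"""Synthetic Mediterranean weather and model-consistent phenology observations.

The weather generator emulates the thermal structure of Italian olive
sites: a sinusoidal annual cycle of the daily mean temperature with its
minimum in mid-February, an AR(1) day-to-day anomaly, and a fixed diurnal
range split symmetrically into tmin/tmax.  Defaults place the annual mean
at 17 °C with a 10 °C amplitude — February means near 7 °C and August
means near 27 °C, the envelope typical of Mediterranean lowland sites
(annual means roughly 14–19 °C across a north–south network).

Observation sets are generated by running the forward phenology chain on
that weather and adding rounded Gaussian day noise, so every calibration
and cross-validation routine can be exercised against a known truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import PhenoObservation
from .errors import DataError
from .forcing import predict_chain
from .params import CultivarParams, cultivar_parameter_table, mean_phase_dates
from .weather import WeatherSeries, build_dormancy_season

__all__ = [
    "SiteClimate",
    "SyntheticObservationSet",
    "simulate_weather",
    "simulate_site_network",
    "simulate_observations",
    "packaged_fixtures",
]


@dataclass(frozen=True)
class SiteClimate:
    """Parameters of the synthetic site climate.

    annual_mean : °C, long-term mean of the daily mean temperature.
    annual_amplitude : °C, half peak-to-trough of the annual cycle.
    coldest_day : day of year of the cycle minimum (46 ~ mid-February).
    diurnal_range : °C, tmax − tmin, constant by construction.
    ar1_rho : lag-1 autocorrelation of the daily anomaly, in [0, 1).
    noise_sd : °C, stationary s.d. of the anomaly.
    """

    annual_mean: float = 17.0
    annual_amplitude: float = 10.0
    coldest_day: int = 46
    diurnal_range: float = 8.0
    ar1_rho: float = 0.7
    noise_sd: float = 2.0
    seed: int = 0
    site_id: str = "synthetic"
    latitude: float = 40.0
    longitude: float = 9.0

    def __post_init__(self) -> None:
        if not self.annual_amplitude > 0:
            raise DataError("annual_amplitude must be > 0")
        if not self.diurnal_range > 0:
            raise DataError("diurnal_range must be > 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise DataError("ar1_rho must lie in [0, 1)")


def simulate_weather(site: SiteClimate, years: tuple[int, int]) -> WeatherSeries:
    """Generate a contiguous daily series covering calendar years [y0, y1].

    The daily mean follows m(d) = annual_mean − amplitude·cos(2π(d −
    coldest_day)/365.25) plus a stationary AR(1) anomaly; the same anomaly
    shifts tmin and tmax so the diurnal range is preserved exactly.
    """
    y0, y1 = years
    dates = pd.date_range(dt.date(y0, 1, 1), dt.date(y1, 12, 31))
    doy = dates.day_of_year.to_numpy(dtype=float)
    mean_cycle = site.annual_mean - site.annual_amplitude * np.cos(
        2.0 * np.pi * (doy - site.coldest_day) / 365.25
    )
    rng = np.random.default_rng(site.seed)
    n = len(dates)
    anomaly = np.zeros(n)
    if site.noise_sd > 0:
        innovations = rng.normal(0.0, site.noise_sd, size=n)
        scale = np.sqrt(1.0 - site.ar1_rho**2)
        anomaly[0] = innovations[0]
        for t in range(1, n):
            anomaly[t] = site.ar1_rho * anomaly[t - 1] + scale * innovations[t]
    tmean = mean_cycle + anomaly
    half = site.diurnal_range / 2.0
    frame = pd.DataFrame(
        {"tmin": tmean - half, "tmax": tmean + half}, index=dates
    )
    return WeatherSeries(
        site_id=site.site_id,
        latitude=site.latitude,
        longitude=site.longitude,
        frame=frame,
    )


def _child_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + 7919 * (k + 1)) % (2**31)


def simulate_site_network(
    base: SiteClimate, offsets: Sequence[float], years: tuple[int, int]
) -> list[WeatherSeries]:
    """One synthetic site per annual-mean offset (°C), with distinct sub-seeds.

    Emulates a multi-site network spanning a few degrees of annual-mean
    temperature, like an Italian transect from warm coastal Sicily to the
    cooler central hills.
    """
    if len(offsets) == 0:
        raise DataError("offsets must be nonempty")
    series = []
    for k, off in enumerate(offsets):
        site = replace(
            base,
            annual_mean=base.annual_mean + float(off),
            seed=_child_seed(base.seed, k),
            site_id=f"{base.site_id}_{k}",
        )
        series.append(simulate_weather(site, years))
    return series


@dataclass
class SyntheticObservationSet:
    """Phenology observations generated by the forward model plus day noise."""

    true_params: CultivarParams
    observations: list[PhenoObservation]
    obs_noise_sd: float
    seed: int
    n_failed: int = 0
    seasons: dict = field(default_factory=dict, repr=False)  # (site, year) -> season


def simulate_observations(
    cv: CultivarParams,
    weather: Sequence[WeatherSeries],
    years: Sequence[int],
    obs_noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticObservationSet:
    """Run the forward chain per site-year and emit noisy observations.

    Gaussian day noise (s.d. ``obs_noise_sd``) is added to each successful
    phase date and rounded to whole days, since phenological observations
    are calendar dates.  Site-years where the model fails (requirements
    never met) are dropped and counted in ``n_failed``.
    """
    rng = np.random.default_rng(seed)
    observations: list[PhenoObservation] = []
    seasons: dict = {}
    n_failed = 0
    for series in weather:
        for year in years:
            season = build_dormancy_season(series, year)
            chain = predict_chain(season, cv)
            if not chain.all_success:
                n_failed += 1
                continue
            seasons[(series.site_id, year)] = season
            jdays = {}
            for phase, pred in (
                ("sprouting", chain.sprouting),
                ("blooming", chain.blooming),
                ("pit_hardening", chain.pit_hardening),
            ):
                noisy = pred.jday
                if obs_noise_sd > 0:
                    noisy = int(round(pred.jday + rng.normal(0.0, obs_noise_sd)))
                jdays[phase] = max(1, noisy)
            for phase in ("sprouting", "blooming", "pit_hardening"):
                observations.append(
                    PhenoObservation(
                        site_id=series.site_id,
                        cultivar=cv.cultivar,
                        phase=phase,
                        year=year,
                        jday=jdays[phase],
                        sprouting_jday=jdays["sprouting"],
                    )
                )
    if not observations:
        raise DataError(
            "every site-year failed to fulfil the chilling/heating "
            "requirements; use warmer climate or laxer parameters"
        )
    return SyntheticObservationSet(
        true_params=cv,
        observations=observations,
        obs_noise_sd=obs_noise_sd,
        seed=seed,
        n_failed=n_failed,
        seasons=seasons,
    )


def simulate_climatology_grid(
    base: SiteClimate,
    latitudes: Sequence[float],
    longitudes: Sequence[float],
    lapse_per_degree: float = -0.8,
) -> "TemperatureGrid":
    """Noise-free climatology grid with a south-to-north cooling gradient.

    Each cell's 365-day mean year follows the site's sinusoidal cycle with
    the annual mean shifted by ``lapse_per_degree`` (°C per degree of
    latitude northward; negative means the north is colder, the typical
    Mediterranean meridional gradient).  Longitude has no effect, so rows
    are spatially constant — convenient for monotonicity checks.
    """
    import xarray as xr

    from .weather import TemperatureGrid

    lats = np.asarray(latitudes, dtype=float)
    lons = np.asarray(longitudes, dtype=float)
    doy = np.arange(1, 366, dtype=float)
    cycle = -base.annual_amplitude * np.cos(
        2.0 * np.pi * (doy - base.coldest_day) / 365.25
    )
    mean_by_lat = base.annual_mean + lapse_per_degree * (lats - lats.min())
    tmean = cycle[:, None, None] + mean_by_lat[None, :, None] + np.zeros(len(lons))
    half = base.diurnal_range / 2.0
    ds = xr.Dataset(
        {
            "tmin": (("dayofyear", "lat", "lon"), tmean - half),
            "tmax": (("dayofyear", "lat", "lon"), tmean + half),
        },
        coords={"dayofyear": np.arange(1, 366), "lat": lats, "lon": lons},
    )
    return TemperatureGrid(dataset=ds, kind="climatology")


def packaged_fixtures() -> dict[str, pd.DataFrame]:
    """The packaged reference tables: mean phase dates and calibrated parameters."""
    return {
        "mean_dates": mean_phase_dates(),
        "parameters": cultivar_parameter_table(),
    }
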