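import datetime as dt

import numpy as np
import pandas as pd
import pytest

import olivephen as op


def make_weather_frame(start, n_days, tmin, tmax):
    dates = pd.date_range(start, periods=n_days)
    return pd.DataFrame({"tmin": float(tmin), "tmax": float(tmax)}, index=dates)


def segmented_season(phenology_year, segments):
    """Build a DormancySeason from (n_days, tmin, tmax) segments.

    The last segment is stretched to fill the Nov-Oct window.
    """
    start = dt.date(phenology_year - 1, 11, 1)
    end = dt.date(phenology_year, 10, 31)
    total = (end - start).days + 1
    tmin, tmax = [], []
    for n, lo, hi in segments:
        tmin += [float(lo)] * n
        tmax += [float(hi)] * n
    if len(tmin) < total:
        n_fill = total - len(tmin)
        _, lo, hi = segments[-1]
        tmin += [float(lo)] * n_fill
        tmax += [float(hi)] * n_fill
    frame = pd.DataFrame(
        {"tmin": tmin[:total], "tmax": tmax[:total]},
        index=pd.date_range(start, end),
    )
    return op.DormancySeason(phenology_year=phenology_year, frame=frame)


@pytest.fixture(scope="session")
def carolea():
    return op.cultivar_params("Carolea")


@pytest.fixture(scope="session")
def site_network():
    """Four synthetic Mediterranean sites with annual means 14-18.5 degC.

    The spread mirrors a north-south Italian network and gives the
    chilling model distinctly different thermal regimes to calibrate on.
    """
    base = op.SiteClimate(seed=7)
    return op.simulate_site_network(base, [-3.0, -1.5, 0.0, 1.5], (1995, 2000))


@pytest.fixture(scope="session")
def clean_obsset(carolea, site_network):
    """Noise-free observations for 8 site-years (4 sites x 2 phenology years)."""
    return op.simulate_observations(
        carolea, site_network, range(1998, 2000), obs_noise_sd=0.0, seed=3
    )


@pytest.fixture(scope="session")
def clean_sprouting(clean_obsset):
    sp = [o for o in clean_obsset.observations if o.phase == "sprouting"]
    seasons = [clean_obsset.seasons[(o.site_id, o.year)] for o in sp]
    return seasons, np.array([o.jday for o in sp])
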