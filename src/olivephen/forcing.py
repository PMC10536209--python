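"""Growing-degree-day forcing from a dynamic start date, and the full
chill-then-force phenology chain.

Daily forcing is GDD = (Tx' + Tn')/2 - Tb where Tx' and Tn' are the daily
extremes clamped into [Tb, Tx.base] *before* averaging: temperatures below
the base contribute nothing and temperatures above the upper threshold are
capped, because growth is inefficient outside that window.  Forcing for a
phase accumulates from the day after its start event (the sprouting date)
until the heating requirement Hr is reached.

The combined chain predicts sprouting with the chill/anti-chill model and
then accumulates GDD from the sprouting date with phase-specific heating
requirements for blooming and pit hardening — both measured from sprouting,
not chained bloom-to-pit, so a single calibrated thermal window (Tb,
Tx.base) serves both later phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chill import PhasePrediction, predict_sprouting
from .errors import ValidationError, WindowError
from .params import CultivarParams, GDDParams
from .weather import DormancySeason

__all__ = [
    "GDDTrajectory",
    "PhenologyChain",
    "daily_gdd",
    "fulfillment_index_from_units",
    "accumulate_gdd",
    "predict_phase_date",
    "predict_chain",
]


def daily_gdd(tmin, tmax, params: GDDParams) -> np.ndarray | float:
    """Clamped daily growing-degree-day forcing; always >= 0.

    Accepts scalars or arrays (vectorised).
    """
    tn = np.asarray(tmin, dtype=float)
    tx = np.asarray(tmax, dtype=float)
    if np.any(tn > tx):
        raise ValidationError("tmin > tmax")
    tn_c = np.clip(tn, params.tb, params.tx_base)
    tx_c = np.clip(tx, params.tb, params.tx_base)
    gdd = (tx_c + tn_c) / 2.0 - params.tb
    if np.isscalar(tmin) and np.isscalar(tmax):
        return float(gdd)
    return gdd


@dataclass
class GDDTrajectory:
    """Daily forcing and its cumulative sum from the start day onward."""

    dates: pd.DatetimeIndex
    jdays: np.ndarray
    gdd: np.ndarray  # zero before and on the start day
    cumulative: np.ndarray
    start_index: int
    fulfillment_index: int | None

    @property
    def fulfillment_day(self):
        if self.fulfillment_index is None:
            return None
        return self.dates[self.fulfillment_index].date()


def fulfillment_index_from_units(
    gdd: np.ndarray, start_index: int, hr: float
) -> int | None:
    """Index of the first day whose cumulative forcing (from the day after
    ``start_index``) reaches ``hr``, or None."""
    g = gdd.copy()
    g[: start_index + 1] = 0.0
    done = np.cumsum(g) >= hr
    return int(np.argmax(done)) if done.any() else None


def _start_index(season: DormancySeason, start) -> int:
    """Locate a start expressed as a phenology-year jday or a date."""
    if isinstance(start, (int, np.integer)):
        hits = np.flatnonzero(season.jdays == int(start))
        if len(hits) == 0:
            raise WindowError(
                f"start jday {start} outside season jdays "
                f"[{season.jdays[0]}, {season.jdays[-1]}]"
            )
        return int(hits[0])
    ts = pd.Timestamp(start)
    if ts < season.dates[0] or ts > season.dates[-1]:
        raise WindowError(f"start date {ts.date()} outside season window")
    return int(season.dates.get_loc(ts))


def accumulate_gdd(season: DormancySeason, start, params: GDDParams) -> GDDTrajectory:
    """Accumulate forcing from the day after *start* until Hr is reached.

    The event day itself contributes no forcing: it marks the end of that
    day's developmental state.
    """
    i0 = _start_index(season, start)
    gdd = np.asarray(daily_gdd(season.tmin, season.tmax, params), dtype=float)
    fulfillment = fulfillment_index_from_units(gdd, i0, params.hr)
    gdd[: i0 + 1] = 0.0
    cumulative = np.cumsum(gdd)
    return GDDTrajectory(
        dates=season.dates,
        jdays=season.jdays,
        gdd=gdd,
        cumulative=cumulative,
        start_index=i0,
        fulfillment_index=fulfillment,
    )


def predict_phase_date(
    season: DormancySeason, start, params: GDDParams, phase: str
) -> PhasePrediction:
    """Predict a forcing-driven phase date from a start event."""
    traj = accumulate_gdd(season, start, params)
    if traj.fulfillment_index is None:
        return PhasePrediction(phase=phase, status="requirement-not-met")
    return PhasePrediction(
        phase=phase, status="success", jday=int(traj.jdays[traj.fulfillment_index])
    )


@dataclass(frozen=True)
class PhenologyChain:
    """Predicted sprouting, blooming and pit-hardening dates for one season."""

    sprouting: PhasePrediction
    blooming: PhasePrediction
    pit_hardening: PhasePrediction

    @property
    def all_success(self) -> bool:
        return self.sprouting.ok and self.blooming.ok and self.pit_hardening.ok

    def jdays(self) -> tuple[int | None, int | None, int | None]:
        return (self.sprouting.jday, self.blooming.jday, self.pit_hardening.jday)


def predict_chain(
    season: DormancySeason,
    cv: CultivarParams,
    start_override: int | None = None,
) -> PhenologyChain:
    """Run the full chill-then-force chain over one season.

    ``start_override`` substitutes an observed sprouting jday for the
    modelled one (used when calibrating the forcing stages against
    observations, where the previous phase's date is known).
    """
    if start_override is not None:
        sprouting = PhasePrediction(
            phase="sprouting", status="success", jday=int(start_override)
        )
    else:
        sprouting = predict_sprouting(season, cv.cac)
    if not sprouting.ok:
        failed = PhasePrediction(phase="blooming", status="requirement-not-met")
        failed_pit = PhasePrediction(phase="pit_hardening", status="requirement-not-met")
        return PhenologyChain(sprouting=sprouting, blooming=failed,
                              pit_hardening=failed_pit)
    blooming = predict_phase_date(season, sprouting.jday, cv.gdd_bloom, "blooming")
    pit = predict_phase_date(season, sprouting.jday, cv.gdd_pit, "pit_hardening")
    return PhenologyChain(sprouting=sprouting, blooming=blooming, pit_hardening=pit)
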