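"""Chill and anti-chill days: the six-case single-triangle formulas and
sequential dormancy accumulation.

The daily course of temperature is idealised as a triangle rising from the
minimum Tn to the maximum Tx and back over one day.  Chill days (Cd <= 0)
measure the clipped area of that triangle lying between 0 °C and the
threshold Tc; anti-chill days (Ca >= 0) the area above Tc.  Which closed
form applies depends on where Tn and Tx sit relative to 0 and Tc:

====  ====================  =============================================  =========================
case  condition             Cd                                             Ca
====  ====================  =============================================  =========================
1     0 <= Tc <= Tn <= Tx   0                                              Tm - Tc
2     0 <= Tn <= Tc < Tx    -((Tm - Tn) - (Tx - Tc)^2 / (2 (Tx - Tn)))     (Tx - Tc)^2 / (2 (Tx - Tn))
3     0 <= Tn <= Tx <= Tc   -(Tm - Tn)                                     0
4     Tn < 0 <= Tx <= Tc    -Tx^2 / (2 (Tx - Tn))                          0
5     Tn < 0 < Tc < Tx      -(Tx^2 - (Tx - Tc)^2) / (2 (Tx - Tn))          (Tx - Tc)^2 / (2 (Tx - Tn))
6     Tn <= Tx < 0 < Tc     0                                              0
====  ====================  =========================================================================

with Tm = (Tx + Tn)/2.  Case 5's Cd is written so that the six cases join
continuously (it equals the area between 0 and Tc exactly, matching the
numeric triangle integral); case 6 covers days entirely below freezing.

Dormancy is sequential: starting 1 November, only Cd accumulates until the
running sum S reaches the chilling requirement Cr (endo-dormancy release);
from the next day only Ca accumulates until S returns to zero, which marks
sprouting.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .errors import ValidationError
from .params import CACParams
from .weather import DormancySeason

__all__ = [
    "DailyChillResult",
    "CACTrajectory",
    "PhasePrediction",
    "chill_anti_chill",
    "daily_chill_units",
    "sprouting_index_from_units",
    "triangle_oracle",
    "accumulate_cac",
    "predict_sprouting",
]


@dataclass(frozen=True)
class DailyChillResult:
    """One day's chill (Cd <= 0) and anti-chill (Ca >= 0) units plus the case index."""

    cd: float
    ca: float
    case_index: int


@dataclass(frozen=True)
class PhasePrediction:
    """A predicted phenological date, or an explicit requirement-not-met failure.

    ``jday`` is the Julian day within the phenology year (Jan 1 = 1;
    non-positive for dates in the preceding November–December).
    """

    phase: str
    status: str  # "success" | "requirement-not-met"
    jday: int | None = None

    def __post_init__(self) -> None:
        if (self.status == "success") != (self.jday is not None):
            raise ValidationError("status=success iff jday is present")

    @property
    def ok(self) -> bool:
        return self.status == "success"


def _case_indices(tn: np.ndarray, tx: np.ndarray, tc: float) -> np.ndarray:
    """Assign every (Tn, Tx) day to exactly one of the six cases."""
    case = np.empty(tn.shape, dtype=np.int64)
    below = tx < 0
    frost = (~below) & (tn < 0)
    mild = ~below & ~frost  # tn >= 0
    case[below] = 6
    case[frost & (tx <= tc)] = 4
    case[frost & (tx > tc)] = 5
    case[mild & (tn >= tc)] = 1
    case[mild & (tn < tc) & (tx <= tc)] = 3
    case[mild & (tn < tc) & (tx > tc)] = 2
    return case


def daily_chill_units(
    tmin, tmax, tc: float, tmean=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised six-case chill/anti-chill computation.

    Returns (cd, ca, case_index) arrays.  ``tmean`` optionally substitutes a
    supplied daily mean for (Tx+Tn)/2 in the cases whose formulas use Tm
    (1–3); the default symmetric mean is what makes the closed forms agree
    exactly with the triangle integral.
    """
    tn = np.asarray(tmin, dtype=float)
    tx = np.asarray(tmax, dtype=float)
    if np.any(tn > tx):
        raise ValidationError("tmin > tmax")
    if not tc > 0:
        raise ValidationError(f"tc must be > 0, got {tc}")
    tm = (tx + tn) / 2.0
    if tmean is not None:
        tm_user = np.asarray(tmean, dtype=float)
    case = _case_indices(tn, tx, tc)

    span = tx - tn
    # Quadratic terms are only consumed where their case applies; those cases
    # all force span > 0, so the guarded denominator never leaks a value.
    safe = np.where(span > 0, span, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        above = np.where(span > 0, (tx - tc) ** 2 / (2.0 * safe), 0.0)  # area above Tc
        above0 = np.where(span > 0, tx**2 / (2.0 * safe), 0.0)  # area above 0 °C

    cd = np.zeros_like(tn)
    ca = np.zeros_like(tn)
    use_tm = tm_user if tmean is not None else tm
    m = case == 1
    ca[m] = use_tm[m] - tc
    m = case == 2
    cd[m] = -((use_tm[m] - tn[m]) - above[m])
    ca[m] = above[m]
    m = case == 3
    cd[m] = -(use_tm[m] - tn[m])
    m = case == 4
    cd[m] = -above0[m]
    m = case == 5
    cd[m] = -(above0[m] - above[m])
    ca[m] = above[m]
    return cd, ca, case


def chill_anti_chill(
    tmin: float, tmax: float, tc: float, tmean: float | None = None
) -> DailyChillResult:
    """Chill and anti-chill units for a single day (scalar convenience)."""
    cd, ca, case = daily_chill_units(
        np.atleast_1d(tmin), np.atleast_1d(tmax), tc,
        None if tmean is None else np.atleast_1d(tmean),
    )
    return DailyChillResult(cd=float(cd[0]), ca=float(ca[0]), case_index=int(case[0]))


def triangle_oracle(
    tmin: float, tmax: float, tc: float, n_steps: int = 10_000
) -> DailyChillResult:
    """Numerically integrate the diurnal triangle curve (test oracle).

    The idealised temperature curve T(t) rises linearly from Tn to Tx over
    the first half of the day and falls back over the second half.  Then

    * Ca = integral of max(0, T - Tc) dt,
    * Cd = -integral of max(0, min(T, Tc) - max(Tn, 0)) dt.

    A zero-width triangle (Tn = Tx) has zero area, hence Cd = Ca = 0 unless
    the constant line itself exceeds Tc.
    """
    if tmin > tmax:
        raise ValidationError("tmin > tmax")
    if n_steps < 1000:
        raise ValidationError("n_steps must be >= 1000 for a trustworthy oracle")
    t = np.linspace(0.0, 1.0, n_steps + 1)
    temp = np.where(t <= 0.5, tmin + 2 * t * (tmax - tmin),
                    tmax - 2 * (t - 0.5) * (tmax - tmin))
    ca = float(np.trapezoid(np.maximum(0.0, temp - tc), t))
    floor = max(tmin, 0.0)
    cd = -float(np.trapezoid(np.maximum(0.0, np.minimum(temp, tc) - floor), t))
    case = int(_case_indices(np.atleast_1d(float(tmin)),
                             np.atleast_1d(float(tmax)), tc)[0])
    return DailyChillResult(cd=cd, ca=ca, case_index=case)


def sprouting_index_from_units(
    cd: np.ndarray, ca: np.ndarray, cr: float
) -> tuple[int | None, int | None]:
    """Endo-release and sprouting indexes of the sequential accumulation.

    Phase 1 sums only Cd until the running total reaches Cr; phase 2 sums
    only Ca from the next day until the total returns to zero.  Either index
    is None when the corresponding requirement is never met.
    """
    s1 = np.cumsum(cd)
    hit = s1 <= cr
    if not hit.any():
        return None, None
    release = int(np.argmax(hit))
    s2 = s1[release] + np.cumsum(ca[release + 1:])
    done = s2 >= 0.0
    if not done.any():
        return release, None
    return release, release + 1 + int(np.argmax(done))


@dataclass
class CACTrajectory:
    """Sequential chill/anti-chill accumulation over one dormancy season.

    ``cumulative`` follows the two-phase bookkeeping: during endo-dormancy it
    is the running sum of Cd only (non-increasing); after release it is
    S(release) plus the running sum of Ca only (non-decreasing).
    """

    dates: pd.DatetimeIndex
    cd: np.ndarray
    ca: np.ndarray
    cumulative: np.ndarray
    endo_release_index: int | None
    sprouting_index: int | None
    jdays: np.ndarray

    @property
    def endo_release_day(self) -> date | None:
        if self.endo_release_index is None:
            return None
        return self.dates[self.endo_release_index].date()

    @property
    def sprouting_day(self) -> date | None:
        if self.sprouting_index is None:
            return None
        return self.dates[self.sprouting_index].date()

    def to_frame(self) -> pd.DataFrame:
        """Export ``date,cd,ca,cumulative,phase`` for plotting."""
        n = len(self.dates)
        phase = np.full(n, "endo-dormancy", dtype=object)
        if self.endo_release_index is not None:
            phase[self.endo_release_index + 1:] = "eco-dormancy"
            if self.sprouting_index is not None:
                phase[self.sprouting_index:] = "post-sprouting"
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "cd": self.cd,
                "ca": self.ca,
                "cumulative": self.cumulative,
                "phase": phase,
            }
        )


def accumulate_cac(season: DormancySeason, params: CACParams) -> CACTrajectory:
    """Run the sequential chill / anti-chill accumulation over one season."""
    cd, ca, _ = daily_chill_units(season.tmin, season.tmax, params.tc)
    s1 = np.cumsum(cd)
    cumulative = s1.copy()
    release, sprout = sprouting_index_from_units(cd, ca, params.cr)
    if release is not None:
        cumulative[release + 1:] = s1[release] + np.cumsum(ca[release + 1:])
    return CACTrajectory(
        dates=season.dates,
        cd=cd,
        ca=ca,
        cumulative=cumulative,
        endo_release_index=release,
        sprouting_index=sprout,
        jdays=season.jdays,
    )


def predict_sprouting(season: DormancySeason, params: CACParams) -> PhasePrediction:
    """Predict the sprouting date: the first day the cumulative sum returns to zero."""
    traj = accumulate_cac(season, params)
    if traj.sprouting_index is None:
        return PhasePrediction(phase="sprouting", status="requirement-not-met")
    return PhasePrediction(
        phase="sprouting",
        status="success",
        jday=int(traj.jdays[traj.sprouting_index]),
    )
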