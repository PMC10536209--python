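"""Calibration: observation records, error functions, and GA parameter fitting.

The chilling and forcing stages are calibrated separately, each by
minimising the RMSE (in days) between predicted and observed phase dates
over a set of dormancy seasons:

* the chilling objective predicts sprouting with candidate (Tc, Cr);
* the forcing objective accumulates GDD with candidate (Tb, Tx.base, Hr)
  starting from each record's *observed* sprouting date, so forcing errors
  are not confounded with chilling errors.

A season whose requirement is never met contributes the season's final day
(31 October) as its prediction — a finite penalty that grows with how far
the candidate is from feasibility, keeping the optimizer's signal smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chill import predict_sprouting
from .errors import DataError, FormatError, ValidationError
from .forcing import predict_phase_date
from .ga import GAConfig, GAResult, ga_minimize
from .params import (
    DEFAULT_CAC_BOUNDS,
    DEFAULT_GDD_BOUNDS,
    CACParams,
    GDDParams,
    ParameterBounds,
    PHASES,
)
from .weather import DormancySeason

__all__ = [
    "PhenoObservation",
    "CalibrationResult",
    "read_observations",
    "write_observations",
    "predicted_sprouting_jdays",
    "predicted_phase_jdays",
    "cac_objective",
    "gdd_objective",
    "calibrate_cac",
    "calibrate_gdd",
]


@dataclass(frozen=True)
class PhenoObservation:
    """One observed phenological date for a site, cultivar, phase and year."""

    site_id: str
    cultivar: str
    phase: str
    year: int
    jday: int
    sprouting_jday: int | None = None  # required for forcing-stage calibration

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if not 1 <= self.jday <= 366:
            raise ValidationError(f"jday must be in 1..366, got {self.jday}")


def read_observations(source) -> list[PhenoObservation]:
    """Read a ``site,cultivar,phase,year,jday[,sprouting_jday]`` CSV."""
    frame = pd.read_csv(source)
    required = ("site", "cultivar", "phase", "year", "jday")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"observation table missing columns: {', '.join(missing)}")
    has_start = "sprouting_jday" in frame.columns
    out = []
    for _, r in frame.iterrows():
        start = None
        if has_start and pd.notna(r["sprouting_jday"]):
            start = int(r["sprouting_jday"])
        out.append(
            PhenoObservation(
                site_id=str(r["site"]), cultivar=str(r["cultivar"]),
                phase=str(r["phase"]), year=int(r["year"]), jday=int(r["jday"]),
                sprouting_jday=start,
            )
        )
    return out


def write_observations(observations: Sequence[PhenoObservation], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "site": [o.site_id for o in observations],
            "cultivar": [o.cultivar for o in observations],
            "phase": [o.phase for o in observations],
            "year": [o.year for o in observations],
            "jday": [o.jday for o in observations],
            "sprouting_jday": [o.sprouting_jday for o in observations],
        }
    )
    frame.to_csv(path, index=False)


@dataclass
class CalibrationResult:
    """Outcome of one GA calibration run."""

    best_params: CACParams | GDDParams
    best_rmse: float
    fitness_trace: np.ndarray = field(repr=False)
    seed: int = 0
    n_generations: int = 0


def _check_pairs(seasons, observed) -> np.ndarray:
    obs = np.asarray(observed, dtype=float)
    if len(seasons) != len(obs):
        raise DataError(
            f"{len(obs)} observations but {len(seasons)} seasons; each "
            "observation needs its matching season"
        )
    if len(obs) == 0:
        raise DataError("no observations to calibrate on")
    return obs


def predicted_sprouting_jdays(
    seasons: Sequence[DormancySeason], params: CACParams
) -> np.ndarray:
    """Predicted sprouting jday per season; failures become the final-day penalty."""
    out = np.empty(len(seasons))
    for i, season in enumerate(seasons):
        pred = predict_sprouting(season, params)
        out[i] = pred.jday if pred.ok else season.last_jday
    return out


def predicted_phase_jdays(
    seasons: Sequence[DormancySeason],
    starts: Sequence[int],
    params: GDDParams,
    phase: str = "blooming",
) -> np.ndarray:
    """Predicted forcing-phase jday per (season, start); failures penalised."""
    out = np.empty(len(seasons))
    for i, (season, start) in enumerate(zip(seasons, starts)):
        pred = predict_phase_date(season, int(start), params, phase)
        out[i] = pred.jday if pred.ok else season.last_jday
    return out


def cac_objective(
    params: CACParams,
    seasons: Sequence[DormancySeason],
    observed_jdays: Sequence[int],
) -> float:
    """RMSE (days) of predicted vs observed sprouting dates."""
    obs = _check_pairs(seasons, observed_jdays)
    pred = predicted_sprouting_jdays(seasons, params)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def gdd_objective(
    params: GDDParams,
    seasons: Sequence[DormancySeason],
    observed_jdays: Sequence[int],
    starts: Sequence[int],
    phase: str = "blooming",
) -> float:
    """RMSE (days) of predicted vs observed forcing-phase dates."""
    obs = _check_pairs(seasons, observed_jdays)
    if len(starts) != len(seasons):
        raise DataError("each season needs its observed sprouting start")
    pred = predicted_phase_jdays(seasons, starts, params, phase)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def calibrate_cac(
    seasons: Sequence[DormancySeason],
    observed_jdays: Sequence[int],
    bounds: ParameterBounds | None = None,
    config: GAConfig | None = None,
) -> CalibrationResult:
    """Fit (Tc, Cr) by GA to observed sprouting dates."""
    bounds = bounds or DEFAULT_CAC_BOUNDS
    config = config or GAConfig()
    _check_pairs(seasons, observed_jdays)

    def objective(x: np.ndarray) -> float:
        params = CACParams(tc=float(x[0]), cr=float(x[1]))
        return cac_objective(params, seasons, observed_jdays)

    result = ga_minimize(objective, [bounds["tc"], bounds["cr"]], config)
    return CalibrationResult(
        best_params=CACParams(tc=float(result.x[0]), cr=float(result.x[1])),
        best_rmse=result.fun,
        fitness_trace=result.trace,
        seed=result.seed,
        n_generations=result.n_generations,
    )


def calibrate_gdd(
    seasons: Sequence[DormancySeason],
    observed_jdays: Sequence[int],
    starts: Sequence[int],
    bounds: ParameterBounds | None = None,
    config: GAConfig | None = None,
    phase: str = "blooming",
    fixed_thresholds: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Fit forcing parameters by GA to observed phase dates.

    With ``fixed_thresholds=(tb, tx_base)`` only the heating requirement Hr
    is optimised — the scheme used for pit hardening, which reuses the
    thermal window calibrated on blooming.
    """
    bounds = bounds or DEFAULT_GDD_BOUNDS
    config = config or GAConfig()
    _check_pairs(seasons, observed_jdays)

    if fixed_thresholds is None:
        def objective(x: np.ndarray) -> float:
            params = GDDParams(tb=float(x[0]), tx_base=float(x[1]), hr=float(x[2]))
            return gdd_objective(params, seasons, observed_jdays, starts, phase)

        box = [bounds["tb"], bounds["tx_base"], bounds["hr"]]
        result = ga_minimize(objective, box, config)
        best = GDDParams(tb=float(result.x[0]), tx_base=float(result.x[1]),
                         hr=float(result.x[2]))
    else:
        tb, tx_base = fixed_thresholds

        def objective(x: np.ndarray) -> float:
            params = GDDParams(tb=tb, tx_base=tx_base, hr=float(x[0]))
            return gdd_objective(params, seasons, observed_jdays, starts, phase)

        result = ga_minimize(objective, [bounds["hr"]], config)
        best = GDDParams(tb=tb, tx_base=tx_base, hr=float(result.x[0]))
    return CalibrationResult(
        best_params=best,
        best_rmse=result.fun,
        fitness_trace=result.trace,
        seed=result.seed,
        n_generations=result.n_generations,
    )
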