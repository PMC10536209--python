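"""Evaluation: RMSE, Taylor-diagram statistics, leave-one-out
cross-validation, and phenology/parameter summary tables.

LOOCV is the validation of choice when observations number in the tens:
each record in turn is held out, the model is recalibrated on the rest, and
the absolute prediction error on the held-out record (the one-observation
RMSE) is logged.  The mean and standard deviation of those fold errors
summarise skill and its variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import clone
from sklearn.model_selection import LeaveOneOut

from .errors import DataError, StatisticsError, ValidationError
from .params import MATURITY_CLASSES

__all__ = [
    "EvalStats",
    "LOOCVResult",
    "rmse",
    "taylor_stats",
    "leave_one_out",
    "loocv",
    "summarize_phenology",
]


def rmse(predicted, observed) -> float:
    """Root mean square error in days."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValidationError(
            f"predicted and observed must have equal nonzero length, "
            f"got {p.shape} and {o.shape}"
        )
    return float(np.sqrt(np.mean((p - o) ** 2)))


@dataclass(frozen=True)
class EvalStats:
    """Taylor-diagram quantities comparing model to observations.

    ``sd_ratio`` is sd(model)/sd(obs); ``centered_rmse_norm`` the centered
    (bias-removed) RMSE divided by sd(obs).  They satisfy the Taylor
    identity crmse² = sd_ratio² + 1 − 2·sd_ratio·r.
    """

    rmse: float
    pearson_r: float
    sd_ratio: float
    centered_rmse_norm: float


def taylor_stats(predicted, observed) -> EvalStats:
    """Pearson r, normalised standard deviation and centered RMSE."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValidationError("need equal-length vectors with at least 3 entries")
    sd_obs = float(np.std(o))
    if sd_obs == 0.0:
        raise StatisticsError("observed series has zero variance")
    sd_mod = float(np.std(p))
    if sd_mod == 0.0:
        r = 0.0  # correlation undefined for a constant prediction
    else:
        r = float(sstats.pearsonr(p, o).statistic)
    crmse = float(np.sqrt(np.mean(((p - p.mean()) - (o - o.mean())) ** 2)))
    return EvalStats(
        rmse=rmse(p, o),
        pearson_r=r,
        sd_ratio=sd_mod / sd_obs,
        centered_rmse_norm=crmse / sd_obs,
    )


@dataclass
class LOOCVResult:
    """Per-fold absolute errors (days) with their mean and standard deviation."""

    fold_errors: np.ndarray = field(repr=False)
    mean: float = 0.0
    stdev: float = 0.0
    n_samples: int = 0

    @classmethod
    def from_errors(cls, errors: Sequence[float]) -> "LOOCVResult":
        e = np.asarray(errors, dtype=float)
        return cls(
            fold_errors=e,
            mean=float(e.mean()),
            stdev=float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            n_samples=len(e),
        )


def leave_one_out(estimator, X, y, starts=None, penalty_jdays=None) -> LOOCVResult:
    """Leave-one-out cross-validation of a phenology estimator.

    For each fold the estimator is cloned, fitted on all but one sample and
    asked to predict the held-out one; the fold error is the absolute
    difference in days.  A failed prediction (NaN) is scored against the
    season's final jday — the same penalty the calibration objectives use —
    so unmet requirements register as large, finite errors.

    ``starts`` (observed sprouting jdays) is split alongside ``X`` for
    forcing-stage estimators that need it.
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 3:
        raise DataError(f"LOOCV needs at least 3 observations, got {n}")
    if len(y) != n:
        raise DataError("X and y length mismatch")
    if penalty_jdays is None:
        penalty_jdays = [season.last_jday for season in X]
    errors = np.empty(n)
    for train_idx, test_idx in LeaveOneOut().split(np.arange(n)):
        k = int(test_idx[0])
        model = clone(estimator)
        X_train = [X[i] for i in train_idx]
        X_test = [X[k]]
        if starts is not None:
            s = np.asarray(starts)
            model.fit(X_train, y[train_idx], starts=s[train_idx])
            pred = model.predict(X_test, starts=s[test_idx])[0]
        else:
            model.fit(X_train, y[train_idx])
            pred = np.asarray(model.predict(X_test)).ravel()[0]
        if np.isnan(pred):
            pred = penalty_jdays[k]
        errors[k] = abs(pred - y[k])
    return LOOCVResult.from_errors(errors)


def loocv(
    seasons,
    observed_jdays,
    kind: str = "cac",
    starts=None,
    bounds=None,
    config: dict | None = None,
) -> LOOCVResult:
    """Convenience wrapper building the estimator for :func:`leave_one_out`.

    ``kind`` selects the model: ``"cac"`` (sprouting), ``"gdd"`` (a forcing
    phase, requires ``starts``).  ``config`` passes GA keyword arguments
    such as population_size / max_generations / random_state.
    """
    from .models import ChillAntiChillModel, DegreeDayModel

    kwargs = dict(config or {})
    if bounds is not None:
        kwargs["bounds"] = bounds
    if kind == "cac":
        return leave_one_out(ChillAntiChillModel(**kwargs), seasons, observed_jdays)
    if kind == "gdd":
        if starts is None:
            raise DataError("kind='gdd' requires starts=")
        return leave_one_out(
            DegreeDayModel(**kwargs), seasons, observed_jdays, starts=starts
        )
    raise DataError(f"unknown model kind {kind!r}")


def summarize_phenology(table: pd.DataFrame, value_columns=None) -> dict[str, pd.DataFrame]:
    """Summary tables by cultivar and maturity class.

    ``table`` must carry ``cultivar`` and ``maturity_class`` columns plus
    numeric value columns (e.g. ``jday`` with a ``phase`` column, or
    parameter columns like ``cr``/``hr_bloom``).  Returns

    * ``by_cultivar`` — per-cultivar (and per-phase, if present) means;
    * ``by_class`` — per-maturity-class means;
    * ``class_difference`` — mid–late minus early means.
    """
    if len(table) == 0:
        raise DataError("empty summary input")
    required = {"cultivar", "maturity_class"}
    if not required.issubset(table.columns):
        raise DataError(f"summary input needs columns {sorted(required)}")
    unknown = set(table["maturity_class"]) - set(MATURITY_CLASSES)
    if unknown:
        raise DataError(f"unknown maturity class(es): {sorted(unknown)}")
    if value_columns is None:
        value_columns = [
            c for c in table.columns
            if c not in ("cultivar", "maturity_class", "phase", "site", "year")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    keys = ["cultivar"] + (["phase"] if "phase" in table.columns else [])
    by_cultivar = table.groupby(keys, sort=False)[value_columns].mean()
    class_keys = ["maturity_class"] + (["phase"] if "phase" in table.columns else [])
    by_class = table.groupby(class_keys, sort=False)[value_columns].mean()
    diff = by_class.xs("mid-late") - by_class.xs("early") if (
        {"early", "mid-late"}.issubset(table["maturity_class"].unique())
    ) else None
    out = {"by_cultivar": by_cultivar, "by_class": by_class}
    if diff is not None:
        out["class_difference"] = (
            diff if isinstance(diff, pd.DataFrame) else diff.to_frame().T
        )
    return out
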