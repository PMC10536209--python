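"""Scikit-learn-style estimators for the chilling and forcing phenology models.

All three estimators take a sequence of :class:`~olivephen.weather.DormancySeason`
objects as ``X`` and Julian-day targets as ``y``, follow the fit/predict
contract with trailing-underscore fitted attributes, and compose with
``sklearn.base.clone`` and the model-selection splitters (``X`` is a plain
Python sequence, which sklearn's indexing utilities handle).

* :class:`ChillAntiChillModel` predicts the sprouting date from (Tc, Cr);
  ``fit`` calibrates the pair with a seeded genetic algorithm.
* :class:`DegreeDayModel` predicts a forcing-driven date (blooming or pit
  hardening) from an observed start date per sample; ``fit`` calibrates
  (Tb, Tx.base, Hr), or only Hr when the thermal window is fixed.
* :class:`PhenologyChainModel` stacks the two: ``y`` is an (n, 3) array of
  sprouting/blooming/pit-hardening jdays and ``predict`` returns the same
  shape, with NaN where a requirement is not met.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .calibrate import (
    calibrate_cac,
    calibrate_gdd,
    predicted_phase_jdays,
    predicted_sprouting_jdays,
)
from .chill import predict_sprouting
from .errors import DataError
from .forcing import predict_phase_date
from .ga import GAConfig
from .params import (
    DEFAULT_CAC_BOUNDS,
    DEFAULT_GDD_BOUNDS,
    CACParams,
    CultivarParams,
    GDDParams,
    ParameterBounds,
)
from .weather import DormancySeason

__all__ = ["ChillAntiChillModel", "DegreeDayModel", "PhenologyChainModel"]


def _validate_seasons(X) -> Sequence[DormancySeason]:
    if isinstance(X, DormancySeason):
        raise DataError("X must be a sequence of DormancySeason, not a single one")
    if len(X) == 0:
        raise DataError("X is empty")
    for i, season in enumerate(X):
        if not isinstance(season, DormancySeason):
            raise DataError(f"X[{i}] is not a DormancySeason")
    return X


def _ga_config(est, seed_offset: int = 0) -> GAConfig:
    seed = 0 if est.random_state is None else int(est.random_state)
    return GAConfig(
        population_size=est.population_size,
        max_generations=est.max_generations,
        crossover_prob=est.crossover_prob,
        mutation_prob=est.mutation_prob,
        n_elites=est.n_elites,
        patience=est.patience,
        seed=(seed + seed_offset) % (2**31),
    )


class ChillAntiChillModel(BaseEstimator, RegressorMixin):
    """Sprouting-date model: sequential chill / anti-chill accumulation.

    Parameters
    ----------
    tc, cr : float
        Threshold temperature (°C) and chilling requirement (negative chill
        units) used by ``predict`` when the model has not been fitted.
    bounds : ParameterBounds, optional
        Search intervals for calibration (defaults: Tc in [7, 14],
        Cr in [-200, -80]).
    population_size, max_generations, crossover_prob, mutation_prob,
    n_elites, patience : genetic-algorithm settings.
    random_state : int, optional
        Seed for the calibration GA; fits are deterministic given the seed.

    Attributes
    ----------
    tc_, cr_ : calibrated parameters after ``fit``.
    rmse_ : training RMSE in days.
    fitness_trace_ : running best RMSE per GA generation.
    """

    def __init__(
        self,
        tc: float = 9.5,
        cr: float = -115.0,
        bounds: ParameterBounds | None = None,
        population_size: int = 50,
        max_generations: int = 1000,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        n_elites: int = 2,
        patience: int = 100,
        random_state: int | None = None,
    ):
        self.tc = tc
        self.cr = cr
        self.bounds = bounds
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.n_elites = n_elites
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y):
        """Calibrate (Tc, Cr) against observed sprouting jdays."""
        X = _validate_seasons(X)
        result = calibrate_cac(
            X, np.asarray(y, dtype=float),
            bounds=self.bounds or DEFAULT_CAC_BOUNDS,
            config=_ga_config(self),
        )
        self.tc_ = result.best_params.tc
        self.cr_ = result.best_params.cr
        self.rmse_ = result.best_rmse
        self.fitness_trace_ = result.fitness_trace
        self.n_generations_ = result.n_generations
        return self

    @property
    def cac_params_(self) -> CACParams:
        return CACParams(tc=getattr(self, "tc_", self.tc),
                         cr=getattr(self, "cr_", self.cr))

    def predict(self, X) -> np.ndarray:
        """Predicted sprouting jday per season; NaN where chilling or forcing
        requirements are never met."""
        X = _validate_seasons(X)
        params = self.cac_params_
        out = np.empty(len(X))
        for i, season in enumerate(X):
            pred = predict_sprouting(season, params)
            out[i] = pred.jday if pred.ok else np.nan
        return out

    def predict_penalized(self, X) -> np.ndarray:
        """Like ``predict`` but failures yield the season's final jday (the
        calibration penalty convention) instead of NaN."""
        X = _validate_seasons(X)
        return predicted_sprouting_jdays(X, self.cac_params_)


class DegreeDayModel(BaseEstimator, RegressorMixin):
    """Forcing-driven phase-date model (blooming or pit hardening).

    ``fit``/``predict`` require ``starts``: the sprouting jday per sample
    from which GDD accumulation begins.  With ``fit_thresholds=False`` the
    thermal window (tb, tx_base) is kept fixed and only the heating
    requirement is calibrated.
    """

    def __init__(
        self,
        tb: float = 5.0,
        tx_base: float = 30.0,
        hr: float = 400.0,
        phase: str = "blooming",
        fit_thresholds: bool = True,
        bounds: ParameterBounds | None = None,
        population_size: int = 50,
        max_generations: int = 1000,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        n_elites: int = 2,
        patience: int = 100,
        random_state: int | None = None,
    ):
        self.tb = tb
        self.tx_base = tx_base
        self.hr = hr
        self.phase = phase
        self.fit_thresholds = fit_thresholds
        self.bounds = bounds
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.n_elites = n_elites
        self.patience = patience
        self.random_state = random_state

    def fit(self, X, y, starts=None):
        """Calibrate forcing parameters against observed phase jdays."""
        X = _validate_seasons(X)
        if starts is None:
            raise DataError("DegreeDayModel.fit requires starts= (sprouting jdays)")
        result = calibrate_gdd(
            X, np.asarray(y, dtype=float), np.asarray(starts, dtype=int),
            bounds=self.bounds or DEFAULT_GDD_BOUNDS,
            config=_ga_config(self),
            phase=self.phase,
            fixed_thresholds=None if self.fit_thresholds else (self.tb, self.tx_base),
        )
        self.tb_ = result.best_params.tb
        self.tx_base_ = result.best_params.tx_base
        self.hr_ = result.best_params.hr
        self.rmse_ = result.best_rmse
        self.fitness_trace_ = result.fitness_trace
        self.n_generations_ = result.n_generations
        return self

    @property
    def gdd_params_(self) -> GDDParams:
        return GDDParams(
            tb=getattr(self, "tb_", self.tb),
            tx_base=getattr(self, "tx_base_", self.tx_base),
            hr=getattr(self, "hr_", self.hr),
        )

    def predict(self, X, starts=None) -> np.ndarray:
        X = _validate_seasons(X)
        if starts is None:
            raise DataError("DegreeDayModel.predict requires starts=")
        params = self.gdd_params_
        out = np.empty(len(X))
        for i, (season, start) in enumerate(zip(X, starts)):
            pred = predict_phase_date(season, int(start), params, self.phase)
            out[i] = pred.jday if pred.ok else np.nan
        return out

    def predict_penalized(self, X, starts=None) -> np.ndarray:
        X = _validate_seasons(X)
        if starts is None:
            raise DataError("DegreeDayModel.predict_penalized requires starts=")
        return predicted_phase_jdays(X, np.asarray(starts, dtype=int),
                                     self.gdd_params_, self.phase)


class PhenologyChainModel(BaseEstimator):
    """Full sprouting -> blooming -> pit-hardening chain for one cultivar.

    ``fit`` calibrates sequentially: (Tc, Cr) on the sprouting column, then
    (Tb, Tx.base, Hr_bloom) on blooming with the observed sprouting dates as
    starts, then Hr_pit alone with the blooming thermal window held fixed.
    ``predict`` runs the chain forward: both later phases accumulate forcing
    from the *modelled* sprouting date.
    """

    def __init__(
        self,
        tc: float = 9.5,
        cr: float = -115.0,
        tb: float = 5.9,
        tx_base: float = 31.5,
        hr_bloom: float = 437.0,
        hr_pit: float = 1074.0,
        cultivar: str = "custom",
        maturity_class: str = "early",
        cac_bounds: ParameterBounds | None = None,
        gdd_bounds: ParameterBounds | None = None,
        population_size: int = 50,
        max_generations: int = 1000,
        crossover_prob: float = 0.8,
        mutation_prob: float = 0.1,
        n_elites: int = 2,
        patience: int = 100,
        random_state: int | None = None,
    ):
        self.tc = tc
        self.cr = cr
        self.tb = tb
        self.tx_base = tx_base
        self.hr_bloom = hr_bloom
        self.hr_pit = hr_pit
        self.cultivar = cultivar
        self.maturity_class = maturity_class
        self.cac_bounds = cac_bounds
        self.gdd_bounds = gdd_bounds
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.n_elites = n_elites
        self.patience = patience
        self.random_state = random_state

    @classmethod
    def from_cultivar_params(cls, cv: CultivarParams, **kwargs) -> "PhenologyChainModel":
        return cls(
            tc=cv.cac.tc, cr=cv.cac.cr,
            tb=cv.gdd_bloom.tb, tx_base=cv.gdd_bloom.tx_base,
            hr_bloom=cv.gdd_bloom.hr, hr_pit=cv.gdd_pit.hr,
            cultivar=cv.cultivar, maturity_class=cv.maturity_class, **kwargs,
        )

    @property
    def cultivar_params_(self) -> CultivarParams:
        g = lambda name: getattr(self, name + "_", getattr(self, name))
        tb, tx_base = g("tb"), g("tx_base")
        return CultivarParams(
            cultivar=self.cultivar,
            maturity_class=self.maturity_class,
            cac=CACParams(tc=g("tc"), cr=g("cr")),
            gdd_bloom=GDDParams(tb=tb, tx_base=tx_base, hr=g("hr_bloom")),
            gdd_pit=GDDParams(tb=tb, tx_base=tx_base, hr=g("hr_pit")),
        )

    def _sub_kwargs(self) -> dict:
        return dict(
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            n_elites=self.n_elites,
            patience=self.patience,
        )

    def fit(self, X, y):
        """Calibrate all three stages from an (n, 3) jday array."""
        X = _validate_seasons(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 3:
            raise DataError("y must be (n_samples, 3): sprouting, blooming, pit")
        seed = 0 if self.random_state is None else int(self.random_state)
        sprout_obs = y[:, 0]

        cac = ChillAntiChillModel(
            bounds=self.cac_bounds, random_state=seed, **self._sub_kwargs()
        ).fit(X, sprout_obs)
        bloom = DegreeDayModel(
            phase="blooming", bounds=self.gdd_bounds, random_state=seed + 1,
            **self._sub_kwargs(),
        ).fit(X, y[:, 1], starts=sprout_obs.astype(int))
        pit = DegreeDayModel(
            tb=bloom.tb_, tx_base=bloom.tx_base_, phase="pit_hardening",
            fit_thresholds=False, bounds=self.gdd_bounds, random_state=seed + 2,
            **self._sub_kwargs(),
        ).fit(X, y[:, 2], starts=sprout_obs.astype(int))

        self.tc_, self.cr_ = cac.tc_, cac.cr_
        self.tb_, self.tx_base_ = bloom.tb_, bloom.tx_base_
        self.hr_bloom_, self.hr_pit_ = bloom.hr_, pit.hr_
        self.rmse_ = {
            "sprouting": cac.rmse_, "blooming": bloom.rmse_,
            "pit_hardening": pit.rmse_,
        }
        self.stages_ = {"sprouting": cac, "blooming": bloom, "pit_hardening": pit}
        return self

    def predict(self, X) -> np.ndarray:
        """(n, 3) array of chain-predicted jdays; NaN where a stage fails."""
        from .forcing import predict_chain  # local import avoids cycle at module load

        X = _validate_seasons(X)
        cv = self.cultivar_params_
        out = np.full((len(X), 3), np.nan)
        for i, season in enumerate(X):
            chain = predict_chain(season, cv)
            for j, pred in enumerate(
                (chain.sprouting, chain.blooming, chain.pit_hardening)
            ):
                if pred.ok:
                    out[i, j] = pred.jday
        return out
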