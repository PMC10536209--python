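"""Model parameter containers, default search bounds, and packaged cultivar tables.

Two parameter families drive the combined phenology model:

* chilling (``CACParams``): a threshold temperature ``tc`` (°C) below which a
  day accumulates chill units and above which it accumulates anti-chill
  units, and a chilling requirement ``cr`` (negative chill units) whose
  fulfilment ends endo-dormancy;
* forcing (``GDDParams``): a base temperature ``tb`` (°C), an upper
  temperature threshold ``tx_base`` (°C) and a heating requirement ``hr``
  (growing-degree-day units) for a phase driven by heat accumulation.

``CultivarParams`` bundles one chilling set and two forcing sets (blooming
and pit hardening, which share the thermal thresholds and differ only in
their heating requirement) for one olive cultivar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import BoundsError, DataError, FormatError

__all__ = [
    "CACParams",
    "GDDParams",
    "CultivarParams",
    "ParameterBounds",
    "DEFAULT_CAC_BOUNDS",
    "DEFAULT_GDD_BOUNDS",
    "mean_phase_dates",
    "cultivar_parameter_table",
    "cultivar_params",
    "read_cultivar_params",
    "write_cultivar_params",
]

PHASES = ("sprouting", "blooming", "pit_hardening")
MATURITY_CLASSES = ("early", "mid-late")


@dataclass(frozen=True)
class CACParams:
    """Chill / anti-chill days parameters.

    Parameters
    ----------
    tc : float
        Threshold temperature in °C, must be positive.
    cr : float
        Chilling requirement in chill units; negative by convention (chill
        units accumulate downward).
    """

    tc: float
    cr: float

    def __post_init__(self) -> None:
        if not self.tc > 0:
            raise BoundsError(f"tc must be > 0 °C, got {self.tc}")
        if not self.cr < 0:
            raise BoundsError(f"cr must be < 0 chill units, got {self.cr}")


@dataclass(frozen=True)
class GDDParams:
    """Growing-degree-day forcing parameters (tb < tx_base, hr > 0)."""

    tb: float
    tx_base: float
    hr: float

    def __post_init__(self) -> None:
        if not self.tb < self.tx_base:
            raise BoundsError(
                f"tb ({self.tb}) must be below tx_base ({self.tx_base})"
            )
        if not self.hr > 0:
            raise BoundsError(f"hr must be > 0 GDD, got {self.hr}")


@dataclass(frozen=True)
class CultivarParams:
    """Full calibrated parameter set for one cultivar.

    Blooming and pit hardening share the same thermal thresholds (tb,
    tx_base); pit hardening has the larger heating requirement because it is
    the later phase.
    """

    cultivar: str
    maturity_class: str
    cac: CACParams
    gdd_bloom: GDDParams
    gdd_pit: GDDParams

    def __post_init__(self) -> None:
        if self.maturity_class not in MATURITY_CLASSES:
            raise DataError(
                f"unknown maturity class {self.maturity_class!r}; "
                f"expected one of {MATURITY_CLASSES}"
            )
        if (self.gdd_pit.tb, self.gdd_pit.tx_base) != (
            self.gdd_bloom.tb,
            self.gdd_bloom.tx_base,
        ):
            raise BoundsError(
                "pit-hardening forcing must share tb/tx_base with blooming"
            )
        if not self.gdd_pit.hr > self.gdd_bloom.hr:
            raise BoundsError(
                "pit-hardening heating requirement must exceed the blooming one"
            )


class ParameterBounds(dict):
    """Per-parameter (lower, upper) real search intervals.

    A thin mapping ``name -> (lo, hi)`` that validates ``lo < hi`` on
    construction and item assignment.
    """

    def __init__(self, mapping: Mapping[str, tuple[float, float]]):
        super().__init__()
        for name, interval in mapping.items():
            self[name] = interval

    def __setitem__(self, name: str, interval: tuple[float, float]) -> None:
        lo, hi = float(interval[0]), float(interval[1])
        if not lo < hi:
            raise BoundsError(
                f"bounds for {name!r} must satisfy lower < upper, got ({lo}, {hi})"
            )
        super().__setitem__(name, (lo, hi))


# Default calibration search intervals for the two parameter families.
DEFAULT_CAC_BOUNDS = ParameterBounds({"tc": (7.0, 14.0), "cr": (-200.0, -80.0)})
DEFAULT_GDD_BOUNDS = ParameterBounds(
    {"tb": (4.0, 10.0), "tx_base": (25.0, 35.0), "hr": (300.0, 1400.0)}
)


def _packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("olivephen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def mean_phase_dates() -> pd.DataFrame:
    """Mean observed phenological dates (JDay) for the four reference cultivars.

    Columns: cultivar, maturity_class, phase, jday.  Early cultivars
    (Carolea, Picholine) sprout around JDay 96–97; mid–late cultivars
    (Frantoio, Moraiolo) around 124–134.
    """
    return _packaged_csv("phenology_mean_dates.csv")


def cultivar_parameter_table() -> pd.DataFrame:
    """Calibrated parameters for the four reference cultivars.

    Columns: cultivar, maturity_class, tc, cr, tb, tx_base, hr_bloom, hr_pit.
    """
    return _packaged_csv("cultivar_parameters.csv")


def cultivar_params(cultivar: str) -> CultivarParams:
    """Look up one reference cultivar's full parameter set by name."""
    table = cultivar_parameter_table()
    row = table[table["cultivar"].str.lower() == cultivar.lower()]
    if row.empty:
        known = ", ".join(table["cultivar"])
        raise DataError(f"unknown cultivar {cultivar!r}; packaged: {known}")
    r = row.iloc[0]
    return CultivarParams(
        cultivar=str(r["cultivar"]),
        maturity_class=str(r["maturity_class"]),
        cac=CACParams(tc=float(r["tc"]), cr=float(r["cr"])),
        gdd_bloom=GDDParams(
            tb=float(r["tb"]), tx_base=float(r["tx_base"]), hr=float(r["hr_bloom"])
        ),
        gdd_pit=GDDParams(
            tb=float(r["tb"]), tx_base=float(r["tx_base"]), hr=float(r["hr_pit"])
        ),
    )


_KV_KEYS = ("cultivar", "class", "tc", "cr", "tb", "tx_base", "hr_bloom", "hr_pit")


def write_cultivar_params(cv: CultivarParams, path: str | Path) -> None:
    """Write a flat ``key = value`` parameter file for one cultivar."""
    lines = [
        f"cultivar = {cv.cultivar}",
        f"class = {cv.maturity_class}",
        f"tc = {cv.cac.tc!r}",
        f"cr = {cv.cac.cr!r}",
        f"tb = {cv.gdd_bloom.tb!r}",
        f"tx_base = {cv.gdd_bloom.tx_base!r}",
        f"hr_bloom = {cv.gdd_bloom.hr!r}",
        f"hr_pit = {cv.gdd_pit.hr!r}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_cultivar_params(path: str | Path) -> CultivarParams:
    """Read a flat ``key = value`` cultivar parameter file."""
    fields: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        fields[key] = value
    missing = [k for k in _KV_KEYS if k not in fields]
    if missing:
        raise FormatError(f"{path}: missing keys: {', '.join(missing)}")
    tb, tx_base = float(fields["tb"]), float(fields["tx_base"])
    return CultivarParams(
        cultivar=fields["cultivar"],
        maturity_class=fields["class"],
        cac=CACParams(tc=float(fields["tc"]), cr=float(fields["cr"])),
        gdd_bloom=GDDParams(tb=tb, tx_base=tx_base, hr=float(fields["hr_bloom"])),
        gdd_pit=GDDParams(tb=tb, tx_base=tx_base, hr=float(fields["hr_pit"])),
    )


def with_cac(cv: CultivarParams, cac: CACParams) -> CultivarParams:
    """Return a copy of *cv* with the chilling parameters replaced."""
    return replace(cv, cac=cac)
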