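# olivephen

Phenology modelling for olive (*Olea europaea* L.) in Mediterranean
climates: forward prediction of **sprouting**, **blooming** and **pit
hardening** dates from daily temperature series, genetic-algorithm
calibration, leave-one-out cross-validation, and gridded spatial
projection.

## Who this is for

Agro-ecologists and crop modellers who have scattered phenological
observations (a handful of site-years per cultivar) and daily
minimum/maximum temperatures — station records or a reanalysis product —
and want a parsimonious, cultivar-specific model of the three main olive
phases that can also be projected over a regional temperature grid.

## The model

Dormancy is handled sequentially with the **chill and anti-chill days**
model. The diurnal temperature course is idealised as a triangle from the
daily minimum Tn up to the maximum Tx and back; with a cultivar threshold
temperature Tc, the clipped triangle areas give daily chill days (Cd ≤ 0,
area between 0 °C and Tc) and anti-chill days (Ca ≥ 0, area above Tc) in
closed form — six mutually exclusive cases depending on where Tn and Tx sit
relative to 0 °C and Tc (a day entirely below freezing contributes
nothing). Starting 1 November, only Cd accumulates until the running sum
reaches the chilling requirement Cr (< 0), releasing endo-dormancy; from
the next day only Ca accumulates until the sum returns to zero, which marks
**sprouting**.

The later phases are forced with **growing degree days** from the
sprouting date:

```
GDD = (Tx' + Tn')/2 − Tb,   Tn', Tx' clamped into [Tb, Tx.base]
```

Blooming occurs when cumulative GDD reaches the phase's heating requirement
Hr_bloom, pit hardening at Hr_pit, both accumulated from the sprouting date
with a shared thermal window (Tb, Tx.base). Parameters (Tc, Cr) and (Tb,
Tx.base, Hr) are calibrated per cultivar by minimising the RMSE (days)
between predicted and observed dates with a seeded real-valued genetic
algorithm under bounded search intervals (defaults: Tc 7–14 °C, Cr −200 to
−80; Tb 4–10 °C, Tx.base 25–35 °C, Hr 300–1400 GDD).

The package ships calibrated parameter sets and mean observed dates for
four reference cultivars — Carolea and Picholine (early budbreak), Frantoio
and Moraiolo (mid–late) — plus a synthetic-weather generator so the whole
workflow runs without any external data.

## Worked example

```python
import olivephen as op

carolea = op.cultivar_params("Carolea")          # packaged reference set
site = op.SiteClimate(annual_mean=17.0, seed=42) # Mediterranean-like site
weather = op.simulate_weather(site, (1996, 1999))
season = op.build_dormancy_season(weather, 1998) # Nov 1997 .. Oct 1998
chain = op.predict_chain(season, carolea)
print("sprouting:     JDay", chain.sprouting.jday)
print("blooming:      JDay", chain.blooming.jday)
print("pit hardening: JDay", chain.pit_hardening.jday)
```

prints

```
sprouting:     JDay 115
blooming:      JDay 157
pit hardening: JDay 196
```

i.e. for this synthetic 17 °C site-year the Carolea chilling requirement
(−115 chill units at Tc = 9.5 °C) is balanced out on day-of-year 115
(late April), 437 GDD more bring blooming on day 157 (early June), and
1074 GDD from sprouting put pit hardening on day 196 (mid-July). The daily
building block is available directly:

```python
op.chill_anti_chill(tmin=-8.0, tmax=-2.0, tc=10.0)  # Cd=0.0, Ca=0.0 (case 6)
op.chill_anti_chill(tmin=2.0, tmax=12.0, tc=10.0)   # Cd=-4.8, Ca=0.2 (case 2)
```

Calibration and validation follow scikit-learn conventions —
`ChillAntiChillModel`, `DegreeDayModel` and `PhenologyChainModel` implement
`fit`/`predict` with `get_params`/`set_params`, so they compose with
`sklearn.base.clone` and the model-selection splitters:

```python
model = op.ChillAntiChillModel(random_state=0).fit(seasons, observed_jdays)
model.tc_, model.cr_, model.rmse_   # calibrated parameters, training RMSE
result = op.loocv(seasons, observed_jdays, kind="cac")
result.mean, result.stdev           # LOOCV skill in days
```

A `click` CLI wraps the same functionality (`olivephen --help`):
`simulate-weather`, `simulate-obs`, `predict`, `calibrate`, `crossval`,
`project`, `diffmap`, `fixtures`.

## Layout

```
src/olivephen/
  weather.py    daily series, dormancy seasons, climatologies, lat/lon grids
  chill.py      six-case chill/anti-chill formulas, triangle oracle, accumulation
  forcing.py    clamped GDD, forcing accumulation, the full chain
  ga.py         seeded real-valued genetic algorithm
  calibrate.py  observations, error functions, GA calibration
  models.py     scikit-learn style estimators
  evaluate.py   RMSE, Taylor statistics, LOOCV, summary tables
  synthetic.py  Mediterranean weather generator, synthetic observations
  spatial.py    gridded projection, difference maps, raster I/O
  cli.py        command-line interface
  data/         packaged reference tables (cultivar parameters, mean dates)
```

See `docs/methods.md` for the modelling assumptions, parameter defaults,
numerical conventions and known limitations.
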