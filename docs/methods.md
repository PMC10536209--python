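# Methods

## Model structure

The package couples two classic temperature-only phenology components in
sequence.

**Chilling stage (sprouting).** The diurnal temperature course is
idealised as a single triangle rising from the daily minimum Tn to the
maximum Tx over half a day and falling back. Given a cultivar threshold
Tc > 0, the triangle area between 0 °C and Tc (counted negative) is the
day's chill days Cd, and the area above Tc is the anti-chill days Ca.
Clipping the triangle at 0 °C and Tc produces six mutually exclusive
closed-form cases determined by the position of Tn and Tx relative to those
two levels; the sixth case (Tx < 0 < Tc) covers days entirely below
freezing, which contribute neither chilling nor forcing. All formulas use
the symmetric mean Tm = (Tx + Tn)/2, which is what makes them agree exactly
with the triangle integral; an option accepts a supplied daily mean in the
cases whose formulas reference Tm. A numeric oracle
(`triangle_oracle`) integrates the triangle directly and is used in tests
to verify every case and every case boundary independently of the closed
forms.

One published rendering of the fifth case subtracts the above-threshold
triangle twice; the implementation uses Cd = −[Tx² − (Tx−Tc)²]/(2(Tx−Tn)),
the only reading that is continuous with the neighbouring cases and equal
to the clipped-area integral. Case selection is exhaustive and exclusive:
the frozen case is taken for Tn ≤ Tx < 0 (closed at Tn = Tx), and the
degenerate zero-width day Tn = Tx falls in a case whose formulas need no
division, so no division-by-zero path exists.

Accumulation is sequential: from 1 November only Cd is summed (Ca ignored)
until the running total S reaches the chilling requirement Cr < 0 —
endo-dormancy release; from the next day only Ca is summed (Cd ignored)
until S ≥ 0, and that day is the sprouting date. S is non-increasing in
phase one and non-decreasing in phase two by construction. If either
crossing has not happened by 31 October the season is reported as
requirement-not-met rather than given an artificial date.

**Forcing stage (blooming, pit hardening).** Daily forcing is
GDD = (Tx′+Tn′)/2 − Tb with Tn and Tx clamped into [Tb, Tx.base]
*separately before averaging*, so GDD ≥ 0 always and additional warmth
above the upper threshold has no effect. Accumulation starts the day
**after** the sprouting date (the event day marks the end of that day's
state; the convention is fixed and one-day shifts are within model error)
and a phase occurs on the first day its cumulative forcing reaches the
heating requirement Hr (≥, no sub-day interpolation — the model is
daily-resolution throughout). Both later phases accumulate from the
sprouting date, not chained bloom-to-pit, and share one thermal window
(Tb, Tx.base) per cultivar; only Hr differs (Hr_pit > Hr_bloom).

## Parameters

| parameter | meaning | units | packaged range (4 cultivars) | search bounds |
|---|---|---|---|---|
| Tc | chilling threshold | °C | 8.2–11.2 | 7–14 |
| Cr | chilling requirement | chill units (< 0) | −137 to −115 | −200 to −80 |
| Tb | forcing base | °C | 4.5–7.0 | 4–10 |
| Tx.base | forcing upper threshold | °C | 26.3–31.5 | 25–35 |
| Hr (bloom) | heating requirement | GDD | 370–568 | 300–1400 |
| Hr (pit) | heating requirement | GDD | 1003–1315 | 300–1400 |

Mid–late cultivars (Frantoio, Moraiolo) carry higher Tc and larger |Cr|
than the early ones (Carolea, Picholine) — a later, more chill-demanding
release — and need fewer GDD to bloom (they start accumulating later in a
warmer part of spring) but more to reach pit hardening.

## Calibration

Each stage is calibrated separately by minimising the RMSE (days) between
predicted and observed dates. The chilling objective predicts sprouting
with candidate (Tc, Cr); the forcing objective accumulates from each
record's *observed* sprouting date, so forcing parameters are not
confounded with chilling errors. Pit hardening reuses the thermal window
calibrated on blooming and fits Hr alone. A season whose requirement is
never met contributes the season's final day (31 Oct) as its prediction — a
finite penalty that grows with distance from feasibility and keeps the
optimizer's ranking informative; forward predictions report explicit
requirement-not-met states instead.

The optimizer is a seeded real-valued genetic algorithm: uniform
initialisation within bounds, tournament selection (size 3), BLX-α
crossover (α = 0.5, probability 0.8), per-gene Gaussian mutation
(probability 0.1, s.d. 10 % of the bound width decaying geometrically by
0.995/generation to a 10⁻⁴ floor), two elites, bound clipping, and early
stop after 100 stagnant generations (cap 1000). The day-scale RMSE surface
is piecewise constant with broad plateaus, a regime where an elitist
population search is a safe default; the contract (seed determinism, bounds
respected, non-worsening trace) is algorithm-agnostic and any bounded
global optimizer could back it. Fits are bit-reproducible given
`random_state`.

Validation follows leave-one-out cross-validation — appropriate when
observations number in the tens — with the absolute held-out error in days
as the fold statistic, summarised by its mean and standard deviation.
Taylor-diagram statistics (Pearson r, sd(model)/sd(obs), centered
RMSE/sd(obs), computed with population standard deviations so the Taylor
identity holds to machine precision) are provided for model comparison.

### Identifiability

(Tc, Cr) are only partially identifiable from sparse observations: many
pairs along a trade-off curve reproduce the same integer date set, so the
calibration contract is *date-level* recovery (every training date within
one day on noise-free synthetic data), not parameter-level recovery. The
plateau shrinks as the training seasons span more varied thermal regimes;
with a network of sites several °C apart in annual mean, held-out dates are
recovered to ≤ 1 day, while two near-identical sites can leave 1–2-day
held-out ambiguity even at zero noise. The packaged test conditions use
four sites with annual means 14–18.5 °C, matching the spread of the
reference observation network.

## Synthetic data

The weather generator emulates Mediterranean site climate: daily mean
m(d) = annual_mean − amplitude·cos(2π(d − coldest_day)/365.25), defaults
17 °C mean, 10 °C amplitude, minimum at day 46 (mid-February) — giving
February means near 7 °C and August means near 27 °C — plus a stationary
AR(1) anomaly (ρ = 0.7, s.d. 2 °C) applied identically to tmin and tmax so
the fixed diurnal range (8 °C) and the tmin ≤ tmax invariant are preserved
exactly. Multi-site networks shift the annual mean per site with distinct
deterministic sub-seeds. Observations are produced by running the forward
chain per site-year and adding Gaussian day noise rounded to whole days
(observations are calendar dates); site-years where the model fails are
dropped, not imputed.

What this does *not* emulate: skewed/heteroscedastic daily anomalies,
weather fronts and cold spells with multi-day structure, spatially
correlated noise between sites, variable diurnal range, or observation
biases of real phenological scoring. Passing recovery tests on this
generator therefore demonstrates the correctness and internal consistency
of the estimation machinery under the model's own assumptions — not field
accuracy for real orchards, which in published applications of this model
family is of order 4–10 days RMSE for forcing-driven phases and worse for
sprouting.

## Spatial projection

For gridded projection each cell's 365-entry day-of-year climatology
(Feb 29 dropped; mean of tmin and tmax per calendar day over a year range,
e.g. 1985–2015) is wrapped into a single November–October "mean year"
season and the chain is run once per cell — matching a long-term-mean
projection that yields one map per phase. A per-year mode (run every
phenology year of a daily grid, then average the successful dates) is
available as a sensitivity check. A failure at any stage masks that stage
and all later stages for the cell, so hyper-cold cells (e.g. alpine grid
points where Tx stays below 0 °C) appear as explicit no-date cells rather
than extrapolated values. Rasters are written as NetCDF with a declared
fill value (−9999) for masked cells; a companion reader restores the mask
losslessly. A 150×150-cell national grid (the 0.1° window spanning roughly
5–20° E, 35–47° N) projects in a few seconds on one CPU via an array-level
fast path that is test-verified to agree cell-for-cell with the per-cell
chain.

## Numerical conventions and edge cases

- Dates in text I/O are ISO-8601; Julian days are counted within the
  phenology year (1 Jan = 1), with non-positive values for November and
  December of the preceding calendar year (1 Nov = −60 in a non-leap year).
- Climatologies always have 365 entries (Feb 29 dropped); real-year
  seasons retain Feb 29, so leap-year seasons have 366 days. A climatology
  wrapped into a leap phenology year repeats 28 February.
- A supplied daily mean must satisfy tmin ≤ tmean ≤ tmax; when absent it is
  derived as (tmin+tmax)/2 and flagged as derived.
- Grid cell lookup is nearest-cell-centre; a point equidistant between two
  centres resolves to the lower index.
- Phase dates are end-of-day crossings (first day the cumulative sum
  crosses the threshold); no sub-day interpolation anywhere.
- Problem sizes in the shipped tests: recovery and cross-validation
  checks use 8 synthetic site-years (4 sites × 2 phenology years) with the
  GA at population 50 and up to 300 generations (noise-free) or population
  30 and 80 generations across 20 replicates (4-day noise); the spatial
  check uses a 120×150-cell gradient grid. These sizes were chosen to
  exercise every code path at full fidelity while keeping the default test
  run quick.

## Known limitations

- Temperature-only: no photoperiod, rainfall, latitude or genotype ×
  environment covariates.
- The chilling stage has the weakest real-world skill in this model family
  (published sprouting errors reach ~20 days for early cultivars); errors
  in the sprouting date propagate into both forcing stages by
  construction.
- The failure penalty (31 Oct) is a calibration device; objective values
  near the penalty magnitude indicate infeasible parameters, not a
  meaningful fit.
- GeoTIFF export and map styling are out of scope; rasters are plain
  NetCDF on regular lat/lon axes with no projection handling.
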