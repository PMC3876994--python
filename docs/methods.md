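# Methods

## Scope and structure

`reefval` projects shallow-water coral cover for three US regions (Hawaii,
South Florida, Puerto Rico) from 2000 to 2100 under two emissions scenarios,
and values the projected declines.  The pipeline has five parts: scenario
expansion (`scenarios`, `carbonate`), the cover simulator (`simulator`),
valuation (`valuation`), synthetic input generation (`synthetic`), and
orchestration/reporting (`pipeline`, `io`, `cli`).

## Scenario expansion

Scenarios are defined by anchor tables: CO₂ (ppm) at 2000/2030/2050/2075/2100
(BAU ends at 785 ppm, reduced emissions at 427 ppm) and warming (°C above
2000) at a handful of years.  Annual values are linear interpolations of the
anchors; outside the anchored range the boundary value is held flat (the
scenarios assume flat emissions after mid-century, and flat padding is the
neutral extension for any partial anchor set).  Monthly SSTs per cell are
the cell's monthly climatological means plus the annual warming — warming
shifts the annual cycle without reshaping it.  Warming anomalies are applied
as per-region scalars; no spatial downscaling or grid smoothing is
performed.  Both scenarios assume a 3 °C equilibrium climate sensitivity;
this is recorded as scenario metadata, not used in any formula.

## Aragonite saturation

The growth model needs Ωa, but only CO₂ and SST are inputs, so Ωa is
computed for surface seawater in equilibrium with atmospheric CO₂ at fixed
total alkalinity (2300 µmol/kg) and salinity (35).  Constants: CO₂
solubility from Weiss (1974); K1/K2 from Lueker et al. (2000, total scale);
boric acid from Dickson (1990); water from Millero (1995); aragonite
solubility from Mucci (1983); total boron from Uppström (1974); calcium
proportional to salinity.  Given [CO₂*], the alkalinity balance reduces to a
quadratic in [H⁺] once the borate and water terms are evaluated at a
provisional pH; two refinement passes give Ωa within 0.1 % of a full
iterative alkalinity–pH root solve over 300–800 ppm × 24–31 °C (the test
suite carries that independent solver as an oracle and asserts agreement
within 5 %).  Users with their own carbonate chemistry can pass any annual
Ωa series directly to the simulator and bypass this module.

## Cover simulation

Monthly multiplicative update, cover capped at 100 % of substrate, no
density dependence.  Net monthly rate `(g·φ(Ωa) − m)/12` with
`φ(Ωa) = clamp(1 − 0.20·(4.6 − Ωa), 0, 1)`; defaults g = m = 0.03/yr mean a
reef at Ωa = 4.6 is in steady state, and each unit of Ωa decline removes
20 % of growth.  `acidification_enabled=False` pins growth at its maximum,
giving exactly zero net rate at defaults — useful as a control.  Temperature
influences the simulation only through bleaching events; an SST-dependent
growth response would be an additional model commitment we do not make.

Bleaching events: six per cell at most, thresholds strictly escalating
(defaults: Hawaii 28.50–29.75 °C in 0.25° steps; Puerto Rico 29.5–30.5 °C
and Florida 30.2–31.2 °C in 0.2° steps — Florida's last two thresholds
continue the 0.2° ladder of the first four).  Trigger probabilities default
to 0.5; bleaching factors (0.5, 0.4, 0.3, 0.3, 0.3, 0.3); mortality factors
(0.3, 0.4, 0.5, 0.5, 0.5, 0.5).  Event detection per year uses the warmest
climatological month's projected mean and that month's interannual SD as a
normal model of the annual warm-season temperature; yearly exceedance
probabilities accumulate independently across years since the previous event
and the accumulator resets after each event.  Heat-dose accumulation over
multiple weeks is deliberately collapsed to threshold exceedance of the
warmest monthly mean — the thresholds are defined as the monthly
temperatures equivalent to the critical dose, which is the only
distributional information the historical-variance inputs carry.

Conventions: at most one event per year (scanning for event *i*+1 starts the
year after event *i*); the event reduction is applied in the warmest
climatological month of the fire year, after that month's growth update;
annual reported cover is the December value; ties in the warmest month
resolve to the earliest month.  With sd = 0 the exceedance probability
degenerates to an indicator, which makes event timing exactly controllable
in tests.

Expected mode (default) is fully deterministic: events fire when cumulative
probability reaches the trigger and remove the expected fraction bf·mf.
Stochastic mode (mandatory seed) draws the fire year against the yearly
probability and realizes the full mf loss with probability bf.  In the test
suite the two modes are compared on a fixture with acidification disabled
and warming far past all six thresholds: there all six events fire with
probability ≈ 1 in both modes and the timing is irrelevant to the final
cover (zero net growth), so the expected-mode product equals the ensemble
mean exactly and the comparison isolates event-loss stochasticity; the
ensemble uses 2000 runs and a 3-standard-error band.

Regional decline is the hardground-area-weighted mean of per-cell
fraction-of-baseline trajectories (baseline = each cell's year-2000
December cover, so the regional fraction is exactly 1.0 in 2000).  A
weighted cell with zero baseline cover is an error, not a silent NaN.

## Valuation

Unit value transfer: consumer surplus per reef visit is the arithmetic mean
($112.35) of eight published US per-day estimates (packaged in
`data/unit_values.csv`); its 95 % CI uses z = 1.96 with the n−1 sample SD —
the normal formula, not Student-t, because that is the formula the printed
interval corresponds to.  Regional baselines: recreation = annual visits ×
unit value (Hawaii 15.5 M visits, Florida 18.2 M; Puerto Rico has no
defensible visit estimate and recreation there is *structurally
unavailable*, never zero); existence value = adult population × $104.93
(Hawaii 0.92 M, Florida 3.89 M, Puerto Rico 2.91 M).  The Florida recreation
product, $2,044.7 M, is reported as computed (the commonly cited rounded
figure of $2,039 M is not reproducible as 18.2 × 112.35; we do not
hard-code it).  Internal arithmetic is full precision; reported tables round
half-away-from-zero to printed precision.

A given percent cover decline causes an equal percent decline in both value
streams (supported by reef-visitation evidence, e.g. an 80 % cover decline
cutting mean trips 2.82 → 0.56).  Streams are discounted to a 2007 base year
at 3 %/yr — years before 2007 compound upward — and summed over 2000–2100.
Recreation and existence PVs are kept separate and never totaled, since the
two categories are neither exhaustive nor independent.  Avoided loss is
PV(policy) − PV(BAU) with identical inputs except the cover series; it is
nonnegative whenever the policy fraction series dominates pointwise.

## Synthetic inputs

The generator emulates the external data the analysis needs: monthly SST
climatologies (sinusoid over the year peaking in August plus a small seeded
per-cell offset, so all cells in a region share one intra-annual shape),
per-cell initial covers (uniform in a preset range), hardground weights
(log-uniform over one decade, to exercise the weighting), and warming
anchors.  Presets are calibrated only to anchored quantities: cover-cell
counts 7/2/2 and hardground-cell counts 14/9/6 for Hawaii/Florida/Puerto
Rico; regional mean initial covers near 38.4 / 11.5 / 24.8 %; and the
thermal regime — Florida (warm-season mean 30.1 °C) and Puerto Rico
(29.4 °C) start at/just below their first thresholds while Hawaii (27.2 °C)
starts 1.3 °C below its own.  Warming anchors are **calibration values, not
published data**: BAU reaches +2.5 °C and the policy scenario +1.0 °C of
warm-season warming by 2100, consistent with the scenarios' CO₂ gap.
Identical seed ⇒ byte-identical bundle; seeds change draws, never structure.

What the synthetic data does *not* emulate: real spatial heterogeneity of
thresholds and climatologies within a region, observed per-cell covers and
hardground areas, trends or autocorrelation in interannual variability, and
the actual downscaled warming fields.  Passing tests therefore demonstrate
the machinery and its qualitative regime behavior (event ordering across
regions, scenario sensitivity of Hawaii, sign and rough scale of avoided
losses), not quantitative projections for real reefs; absolute event years
and dollar values for the real regions are not reproducible without the
original anomaly fields and field data, and the test suite checks structural
properties instead.

## Numerical choices and degenerate inputs

* Interpolation is exact at anchors; duplicate anchor years and single-point
  anchor sets are configuration errors.
* Exceedance probability with sd = 0 is an indicator; negative sd is an
  error.  Probabilities are clamped nowhere — they arise from `norm.sf` and
  products of values in [0, 1].
* Cover is clamped to [0, 100] only via the 100 % cap; it cannot go negative
  because monthly factors and event losses are multiplicative in [0, 1].
* Stochastic substreams: each cell × scenario derives an independent seed
  (< 2³¹) from the study seed via `numpy` `SeedSequence`, so adding cells
  does not perturb other cells' draws.
* Report CSVs round covers to 1e-6 and fractions to 1e-9 to keep files
  byte-stable across platforms.

## Problem sizes

The default study is 11 cells × 2 scenarios × 1212 monthly steps and runs in
about a second.  The stochastic-ensemble check uses 2000 single-cell runs.
Property tests (hypothesis) are derandomized by the library's default seed
policy in CI-style runs.

## Known limitations

* No density dependence, community composition, adaptation, deep-reef
  refugia, or local stressors; events are region-wide within a cell.
* The normal warm-month model ignores heat-dose duration within a year and
  autocorrelation between years.
* Ωa assumes instantaneous air–sea equilibrium and fixed alkalinity.
* Proportional value scaling is a linear approximation; existence values may
  respond nonlinearly to cover loss.
* Existence-value populations are local residents only, and unit values are
  held constant over the century — both conservative.
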