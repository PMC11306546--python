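# Methods

## Model

`chwpay` treats one full-time community health worker (CHW) position as a
cost unit and asks what payment rate makes it self-financing. The monthly
cost stacks three pieces, all linear in their inputs:

* **labor** — CHW hourly wage × annual paid hours (2080 by default);
* **supervision** — one supervisor's wage spread across the team: wage ×
  hours / ratio. Supervision is wage allocation only; any
  supervisor-attributable overhead is assumed to be already folded into the
  per-CHW-hour overhead ledger, which is reported as a single per-CHW figure
  in practice and never as a separate supervisor ledger.
* **overhead** — five per-CHW-work-hour components (equipment, software,
  transportation, space, benefits) × annual hours.

Visit capacity models each visit as a fixed block of the CHW's time: 0.5 h
of visit plus, for in-person visits only, the full round-trip travel time.
With a 1:3 in-person-to-virtual mix the expected time per visit is
`0.5 + 0.25·t`, and capacity is productive monthly hours divided by that.
Break-even rates follow by division: FFS = monthly cost / monthly visits,
PMPM = monthly cost / concurrent panel size. Both are minima — no margin,
no payer mix, no risk adjustment.

### Travel time and double counting

Transportation appears twice in the raw accounting: as dollars (fuel,
maintenance, insurance, depreciation) and as the opportunity cost of the
CHW's hours in transit. Charging the ledger for transit wages *and* shrinking
visit capacity by transit time would bill the same hour twice. The default
configuration therefore treats the transportation ledger component as
vehicle/commute dollars only and realises the opportunity cost solely
through reduced capacity. The switch `travel_opportunity_in_overhead` moves
it the other way: capacity is computed travel-free and the CHW wage for
in-person travel hours (annual visits × in-person share × travel time) is
added to the transportation component. The two modes are alternatives, never
combined.

### Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| annual paid hours | 2080 | h/yr | full-time position |
| supervisor ratio | RN 1:8, MSW 1:6 | CHWs/supervisor | common supervision structures |
| panel size | 65 | patients | base-case concurrent panel |
| enrollment duration | 6 | months | panel turnover reporting only — PMPM revenue depends on concurrent member-months, so duration never enters the thresholds |
| visit duration | 0.5 | h | 30-minute billing unit |
| in-person share | 0.25 | — | 1:3 in-person:virtual mix |
| productive fraction | 1.0 | — | every paid hour is visit or travel time; the most generous (lowest-threshold) assumption, configurable downward |
| CPI factor | 1.0 | — | user input; source dollar-years vary by stream, so no built-in table |

## Uncertainty propagation

Each uncertain input (wages always; overhead components when a sd is
recorded) is drawn independently from a normal distribution around its
geography-level mean, 10,000 draws by default. Draws below $0.01 are
**resampled**, not clipped: clipping would pile probability mass at the
floor and bias means. Credible intervals are empirical percentiles
(2.5/97.5 at the 95% level) of the per-draw thresholds; the point estimate
is the draw mean. The break-even identity (rate × volume = cost) holds
within every draw because each draw's thresholds are computed from that
draw's cost.

Inputs are independent *within* a draw; covariation between inputs is
carried only by geography-level stratification — expensive places have
jointly higher means — not by an estimated covariance matrix.

Reproducibility: one master seed; geography *i* in a table uses the *i*-th
child of `numpy.random.SeedSequence(seed)` with the PCG64 generator, so a
fixed seed yields bit-identical results regardless of how other geographies
are processed, and sensitivity scenarios reuse the same seed so their
differences are purely structural.

### Aggregation

Per-geography estimates are combined into NATIONAL / METRO / NONMETRO rows
as unweighted means by default (employment weights optional — the
appropriate weighting is a reporting choice, not a model fact). Two pooling
modes exist for aggregate intervals:

* `mean` (default): per draw, average thresholds across geographies, then
  take percentiles — the CI of the national *mean*, which narrows as
  geographies accumulate;
* `pooled`: percentiles of all geographies' draws combined — the spread of
  thresholds across places and draws together. Published national intervals
  for quantities of this kind are typically of the pooled type (far wider
  than the CI of the mean), so the acceptance script reports pooled national
  bounds.

### A note on the national PMPM

The national input means used as generator targets (CHW $23.51/h, RN
$39.88/h at 1:8, overhead $43.65 per work-hour, 2080 h) imply a monthly cost
of $12,505 per CHW and hence a national PMPM near $192 at panel 65. A
national PMPM of ~$140 would instead require a monthly cost near $9,112.
Both figures cannot hold under one cost vector; the travel-time calibration
below targets the FFS side, and the package reports the PMPM its cost model
actually implies rather than forcing agreement.

## Synthetic data generator

The generator emulates the statistical shape of real geography tables
(wage-survey extracts by state and metro/non-metro area) without
reconstructing any real area:

* wage means: truncated normals around the national targets (cross-geography
  sds ≈ 3.3/8.0/5.5 $/h for CHW/RN/MSW, chosen to match published
  cross-state ranges of roughly ±2.5 sd);
* overhead totals: log-normal (log-sd 0.5) — observed cross-geography
  overhead ranges are strongly right-skewed, with a long expensive tail;
* transportation share of overhead: Beta with mean 0.651 and concentration
  12 (sd ≈ 0.13), remainder split across the other four components by a
  Dirichlet favouring benefits and space;
* travel time: normal around 0.85 h (metro) / 1.05 h (non-metro), sd 0.15 h.
  The means are **calibrated** so the capacity-implied national FFS lands
  near $53 per visit under default settings — a calibration choice, not an
  observed quantity;
* within-geography sds are not published anywhere; defaults are 25% of the
  wage mean and 40% of each overhead component mean, set once to give
  per-geography CI widths of the order seen in published state-level tables.

What the generator does **not** emulate: real area definitions or state
identities, metro/non-metro wage differentials, spatial correlation between
neighbouring areas, and non-normal within-geography wage distributions.
Tests passing on synthetic tables therefore demonstrate the engine's
arithmetic, invariants and calibration behaviour — not the accuracy of any
real state's threshold, which requires the user's own input table.

## Numerical choices

* Currency is kept at full float precision internally; rounding to cents
  happens only at serialization, so the additivity and break-even identities
  hold to machine precision (verified at < 1e-9 relative error over 500
  geographies × 1,000 draws; observed ~1e-15).
* Fractional visits are never rounded — thresholds are rates, not schedules.
* Panel sweeps rescale every stored draw, so CI bounds move by exactly the
  same factor as the point value; sweeping above the reference panel logs a
  warning because demand-implied volume then exceeds the travel-limited
  capacity the baseline was computed from.
* Aggregation ties CI bounds to the point estimate (`ci_low ≤ mean ≤
  ci_high` is enforced on every constructed estimate).
* Degenerate inputs fail loudly: non-positive wages, zero panel, zero visit
  volume, infeasible generator targets and CI levels outside (0, 1) all
  raise typed errors with located messages.

## Problem sizes

Default runs simulate 104 geographies (52 states × 2 areas) × 10,000 draws
in about a second on one core. The identity and recovery suites use 500
geographies; property suites use 40–50 randomised instances. These sizes
make the sampling-error bounds in the tests (2–3 standard errors) sharp
enough to catch real defects while keeping the full suite under a few
seconds.

## Limitations

Only two supervisor archetypes are modelled; the overhead ledger is assumed
supervisor-inclusive; capacity is a deterministic rate with no scheduling or
no-show modelling; travel time enters as a geography constant without a
recorded sd; and all revenue is single-payer at the threshold rate, with no
payer mix or partial billing.
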