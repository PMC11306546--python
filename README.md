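# chwpay

Break-even Medicaid payment rates for community health worker (CHW) programs.

CHW programs — lay health workers making home and community visits for
Medicaid patients — are increasingly financed through Medicaid itself, either
as fee-for-service (FFS) payments per 30-minute visit (billing code 98960) or
as capitated per-member-per-month (PMPM) payments for every patient on a
CHW's panel. `chwpay` is a geography-stratified microsimulation that answers
the rate-setting question behind both: **what is the minimum payment rate at
which program revenue covers the full cost of employing a CHW?** It is aimed
at health-economics analysts and state/plan actuaries who have geography-keyed
wage and overhead tables (e.g. BLS OEWS extracts) and need defensible
break-even thresholds with uncertainty intervals.

## The model

For one full-time CHW with `H` paid hours per year (default 2080), monthly
cost is

```
C = [ w_chw · H  +  w_sup · H / r  +  (Σ_k o_k) · H ] / 12
```

where `w_chw` is the CHW hourly wage, `w_sup` the supervisor wage allocated
across a team of `r` CHWs (RN care manager at 1:8 by default, MSW at 1:6 in
the swap scenario), and `o_k` are five overhead components per CHW work-hour:
equipment, software, transportation, space, benefits.

Monthly visit capacity with visit duration `d` (0.5 h), in-person share `s`
(0.25, i.e. a 1:3 in-person:virtual mix) and round-trip travel time `t` per
in-person visit is

```
V = (H/12) · f / (d + s·t)
```

(`f` = productive fraction, default 1). The break-even thresholds for a panel
of `P` concurrent patients (default 65) are then

```
FFS  = C / V        PMPM = C / P
```

Uncertainty: every wage and overhead component with a standard deviation is
sampled 10,000 times from a normal distribution (resampled above a $0.01
floor), and the 95% credible interval is the empirical 2.5th–97.5th
percentile range of the per-draw thresholds. Panel-size sensitivity uses the
inverse-panel law `rate' = rate · P / P'`, applied per draw so intervals
rescale exactly with the point value.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from chwpay import (StaffingPlan, ServiceModel, SimulationConfig,
                    fixture_national, total_cost, monthly_visit_capacity,
                    ffs_threshold, pmpm_threshold, simulate_thresholds)

geo = fixture_national()          # synthetic national-composite inputs
plan = StaffingPlan.rn()          # RN supervision, 1 per 8 CHWs, 2080 h/yr
svc = ServiceModel()              # panel 65, 30-min visits, 1:3 in-person:virtual

cost = total_cost(geo, plan)
cap = monthly_visit_capacity(svc, geo.travel_time_per_inperson_visit, plan)
print(f"monthly cost per CHW: ${cost.total_monthly:,.2f}")
print(f"visit capacity:       {cap:.1f} visits/month")
print(f"break-even FFS:       ${ffs_threshold(cost.total_monthly, cap):.2f} per 30-min visit")
print(f"break-even PMPM:      ${pmpm_threshold(cost.total_monthly, svc.panel_size):.2f} per member-month")

est = simulate_thresholds(geo, plan, svc, SimulationConfig(n_draws=10_000, seed=1))
print(f"Monte Carlo FFS:      ${est.ffs_rate:.2f} (95% CI ${est.ffs_ci_low:.2f}, ${est.ffs_ci_high:.2f})")
```

prints

```
monthly cost per CHW: $12,505.13
visit capacity:       235.0 visits/month
break-even FFS:       $53.21 per 30-min visit
break-even PMPM:      $192.39 per member-month
Monte Carlo FFS:      $53.18 (95% CI $35.13, $72.11)
```

The composite geography carries national-mean inputs (CHW $23.51/h, RN
$39.88/h, overhead $43.65 per work-hour with transportation at 65.1% of
overhead): a CHW position costs about $12,500 a month, and at ~235 deliverable
visits a month the program breaks even at about $53 per visit. The Monte Carlo
interval reflects the assumed within-geography wage and overhead dispersion.

## Command line

```sh
chwpay synth --states 52 --seed 7 --out inputs.csv       # synthetic input table
chwpay validate inputs.csv
chwpay run --inputs inputs.csv --out results/ --draws 10000 --seed 1
chwpay sensitivity supervisor --inputs inputs.csv --out results/
chwpay sensitivity panel --inputs inputs.csv --panels 15,65,100 --out results/
chwpay report results/results.csv
```

Each run writes `results.csv` (rates + 95% CIs), `results.json` (with
percentile grids) and a `manifest.json` (config, seed, input checksum) that
makes the run bit-for-bit reproducible.

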