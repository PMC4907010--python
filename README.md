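# edcrowd

Queue-based description and analysis of emergency-department (ED) crowding
from patient-level timestamps.

## The problem

Crowding — treatment demand exceeding the beds and nurses available — is a
persistent hazard in emergency departments, associated with worse outcomes
and higher costs. Many crowding measures need rich administrative data or
bespoke statistical machinery; this package implements a deliberately
*generic* alternative that needs nothing beyond the two most reliable
timestamps every ED records: each patient's arrival and departure.

It is intended for ED researchers, quality-improvement teams and capacity
planners who want a reproducible occupancy analysis from a plain CSV export.

## The method

The study period is cut into half-open intervals of width 30 min (any width
dividing 24 h works). Counting arrivals A(t) and departures D(t) per
interval t, the queue length at the start of each interval follows

    Q(t + 1) = Q(t) + A(t) − D(t),        Q(0) = 0,

a pure bookkeeping recursion — no distributional assumptions. From the Q
series the package derives:

- **Shift maxima** — the largest census in each 8-hour shift (day
  07:00–14:59, evening 15:00–22:59, night 23:00–06:59, operational days
  starting 07:00, Friday/Saturday nights counted as weekend). The first
  three shifts (24 h) are discarded as burn-in so the empty start has washed
  out.
- **Crowding risk** — the empirical probability, per shift × weekday/weekend
  (× season) stratum, that the max queue reaches or exceeds bed capacity
  ("100 % occupancy or more", equality included): the complement of the
  stratum ECDF just below the capacity threshold.
- **Carry-over** — Spearman rank correlations between the max queues of
  successive shifts and days, the signature that lets a long day shift warn
  about the coming evening.
- **Staffing pressure** — max-queue-to-nurse ratios against a duty roster of
  nurse counts per clock band.
- **Distributional diagnostics** — Fisher's index of dispersion
  (variance/mean of the interval counts, 1 under Poisson) and Kruskal–Wallis
  comparisons across strata; ED arrivals are typically over-dispersed, so
  Poisson assumptions elsewhere deserve this check.

If triage and early-warning-score (EWS) timestamps are available, the single
"black-box" queue splits into four clinically meaningful sub-queues
(arrival→triage, triage→first EWS, first→last EWS, last EWS→departure) that
nest exactly inside it. A flow-completeness report shows whether the data
can support the extended model.

A synthetic visit generator (non-homogeneous Poisson or negative-binomial
arrivals, log-normal stays, ordered in-visit timestamps, field-level
missingness) makes every stage testable without hospital data.

## Worked example

```python
from datetime import timedelta
from edcrowd import (SimulationSpec, simulate_ed, make_interval_grid,
                     aggregate_table, max_queue_per_shift, exceedance_risk,
                     fisher_dispersion, carry_over, default_roster)

spec = SimulationSpec(seed=1)          # one synthetic year at the default conditions
records = simulate_ed(spec)
grid = make_interval_grid(spec.period_start, spec.period_end, timedelta(minutes=30))
intervals = aggregate_table(records, grid)
roster = default_roster()              # 19 beds, 4-8 nurses by time band
shifts = max_queue_per_shift(intervals, burn_in_shifts=3, roster=roster)
risk = exceedance_risk(shifts, threshold=roster.bed_capacity)

print(len(records), "visits aggregated into", len(grid), "intervals")
print(risk[["shift", "weekend", "n_shifts", "risk"]].round(3).to_string(index=False))
disp = fisher_dispersion(intervals["A_blackbox"])
print(f"dispersion index {disp.index:.2f} ({disp.verdict}-dispersed, p={disp.p_value:.1e})")
co = carry_over(shifts, "day->evening")
print(f"day->evening carry-over: rho={co.rho:.2f}, p={co.p_value:.1e}, n={co.n_pairs}")
```

prints

```
41278 visits aggregated into 17520 intervals
  shift  weekend  n_shifts  risk
    day    False       260 0.558
    day     True       104 0.596
evening    False       260 0.600
evening     True       104 0.519
  night    False       260 0.008
  night     True       104 0.000
dispersion index 1.77 (over-dispersed, p=0.0e+00)
day->evening carry-over: rho=0.27, p=1.4e-07, n=364
```

Reading: over this synthetic year the queue reached the 19-bed capacity at
least once in roughly 56 % of weekday day shifts and 60 % of weekday evening
shifts, but almost never at night; interval arrival counts had variance
1.77× their mean (clearly not Poisson); and a crowded day shift tended to be
followed by a crowded evening (ρ = 0.27). The same pipeline is available
from the shell:

```sh
edcrowd simulate spec.yaml --seed 1 -o visits.csv
edcrowd aggregate visits.csv -o intervals.csv
edcrowd analyze intervals.csv -o results/
```

Each command writes a JSON manifest (input digests, parameters, seed) next
to its output.

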