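# Methods

## Queue model

A patient is "present" from the electronic registration of arrival to that
of departure. For a fixed interval width *w* (default 30 min; any width
dividing 24 h), the grid tiles the study period with half-open intervals
[s, s + w). Arrivals A(t) and departures D(t) are counted per interval and
the start-of-interval census follows

    Q(t + 1) = Q(t) + A(t) − D(t),   Q(0) = 0.

The recursion is exact integer bookkeeping; the only assumptions are that
the two timestamps are accurate and that nobody is present before the period
starts.

**Boundary conventions.** An event falling exactly on an interval boundary
belongs to the interval *starting* there. This forces the census
interpretation of Q: the queue at interval start *s* consists of records
with `entry < s <= exit` — a patient departing exactly at *s* still counts
at *s*, because that departure is processed during the interval beginning at
*s*. The package ships an independent census oracle (direct counting of who
is present at each start) and property-tests that it equals the recursion
elementwise on randomised record sets; this equality is what pins the
convention down, since any other choice breaks it for boundary events.

**Start-up bias and burn-in.** With Q(0) = 0, patients already in the
department at the period start are invisible, so early Q values understate
the census and can even go negative. Negative values are reported unchanged
(clamping would silently break the conservation identity
ΣA − ΣD = Q(final)) and logged; all shift-level analyses discard the first
three shifts (24 h) by default, by which time essentially every stay has
turned over.

**Extended queues.** Where triage and early-warning-score (EWS) timestamps
exist, the stay splits into four sub-queues (arrival→triage, triage→first
EWS, first→last EWS, last EWS→departure). Because these partition the
half-open stay (arrival, departure], their censuses sum exactly to the
black-box census whenever all five timestamps are present and ordered — a
tested invariant. A record whose timestamps violate the idealised order is
kept (and flagged) but excluded only from the specific queues whose bounds
are inverted; it still contributes fully to the black-box flow.

## Shifts, rosters and summaries

Operational days begin at 07:00; shifts are day (07:00–14:59), evening
(15:00–22:59) and night (23:00–06:59), the night attributed to the
operational day on which it began. Friday and Saturday nights are weekend
nights; day and evening shifts follow the calendar (Saturday/Sunday). Each
(operational day, shift) cell receives the maximum of its member interval
censuses; partial leading/trailing shifts are kept and recognisable by
`n_intervals` < 8 h / w.

Medians and IQRs use linear interpolation between order statistics (so an
IQR of integer maxima can legitimately be 4.25). Patient-to-nurse ratios are
rounded half-away-from-zero to one decimal, computed in exact rational
arithmetic so 20/7 → 2.9 and 7/4 → 1.8 without binary-float surprises.

A shift overlapping several roster bands takes the band covering the
majority of its minutes; the runner-up band's count is reported as an
alternative when it differs. Ties (the weekend day shift splits 240/240 min
between a 7-nurse and an 8-nurse band under the bundled roster) go to the
band covering the shift start, i.e. the staffing in force when the shift
begins.

## Crowding risk

Risk is defined on shift maxima: the share of a stratum's shifts whose max
queue reaches or exceeds the bed capacity — one 30-min interval at or above
100 % occupancy suffices, and equality counts (19 patients in 19 beds is
full). For integer maxima this equals 1 − F(threshold − 1) of the stratum's
empirical CDF, a property the tests verify against `scipy.stats.ecdf`.
Seasons, when stratified, are summer = April–September, winter otherwise.

## Statistical toolkit

*Fisher's index of dispersion*: sample variance over sample mean of the
interval counts; (n − 1)·index is referred to χ²(n − 1). Both tails are
reported (over- and under-dispersion) with verdict at α = 0.05. Calibration
is property-tested: under Poisson simulation the type-I error rate sits
within two Monte-Carlo standard errors of 0.05 across 2,000 replicates of
10,000 draws, and a configured negative-binomial variance/mean ratio of 2 is
recovered within ±0.1 on a half-year of flat-profile intervals.

*Spearman's rho*: Pearson correlation of mid-rank vectors (average ranks for
ties). The two-sided p-value is an exact permutation probability for
n ≤ 10 (full enumeration of the n! pairings, chunked to bound memory) and
the t-approximation with n − 2 df above that; shift-level analyses involve
hundreds of pairs, firmly asymptotic territory. A constant input leaves rho
undefined: (nan, nan) with a warning rather than an exception, so one
degenerate stratum does not abort a batch analysis.

*Carry-over*: pairings day→evening and evening→night within an operational
day, night→day and day→day across consecutive operational days, plus
consecutive-day total arrivals. A missing partner (burn-in boundary, gap in
the record) drops the pair. With exactly two pairs rho (±1) is reported with
an undefined p-value; below two pairs is an error. Under an independent null
the p-values are uniform to Kolmogorov distance < 0.05 across 1,000
simulated years (tested).

*Kruskal–Wallis*: scipy's tie-corrected H with χ²(groups − 1) p-value;
all-identical data (which scipy rejects) is reported as H = 0, p = 1.

No multiple-testing correction is applied; results carry exact p-values and
formatting is left to the caller.

## Synthetic visit generator

The generator emulates the structural features of routine ED flow data that
the analyses depend on, with defaults describing a mid-size ED over one
year (the bundled roster's site):

| parameter | default | meaning |
|---|---|---|
| period | 2013-01-01 07:00 → 2014-01-01 07:00 | one year, 17,520 half-hour intervals |
| daily mean arrivals | 113.9 weekday / 115.2 weekend | ≈ 41,600 visits/year |
| diurnal profile | parametric: quiet nights, 11:00 peak, 18:30 bump | 48 weights per day class, normalised |
| count model | negative binomial, k = 8 | variance = μ(1 + μ/k); moderate over-dispersion |
| length of stay | log-normal, meanlog 4.66, sdlog 0.65 (minutes), truncated [1 min, 48 h] | median ≈ 106 min; ≈ 2.8 % of stays ≤ 30 min, ≈ 5.4 % ≥ 5 h |
| in-visit marks | Dirichlet(1.5, 2, 8, 2.5) fractions of the stay | triage soon after arrival, treatment the longest phase |
| missingness | 0.718 triage, 0.879 first EWS, 0.219 last EWS | per-field independent blanking |
| attributes | age ~ Gamma(2, 19) capped at 105; 46.1 % female; 1.17 % triaged red; 1.49 % trauma | marginal rates typical of a mixed ED |

Arrival counts are drawn per interval with mean = daily mean × profile
weight; arrivals are placed uniformly within the interval at minute
precision; surrogate timestamps sit at cumulative Dirichlet fractions of the
stay, so they are ordered and inside the stay *before* missingness blanks
them field-wise. One integer seed feeds named substreams (counts, placement,
LOS, gaps, missingness, attributes), so changing one probability never
perturbs the other streams, and identical specs give byte-identical CSVs.

**What the generator does not emulate — and what passing tests therefore do
not show.** Visits are independent: there is no service slow-down under
crowding, no day-to-day demand correlation (the simulated day→day and
arrival autocorrelations hover near zero, whereas real EDs show positive
ones), and no dependence between the three missingness fields (real
registration practice is strongly dependent — a site where 71 % of visits
lack *all* surrogates cannot arise from these independent marginals, which
give ≈ 63 %). Tests passing on this generator demonstrate that the
*computations* are correct and calibrated, not that real data will show any
particular effect size. The within-operational-day day→evening carry-over
the simulator does produce (ρ ≈ 0.3) arises mechanically from long stays
spanning shift boundaries.

## Numerical and design choices

- Timestamps are naive local wall-clock at minute precision; no DST
  arithmetic (a year is exactly 365 × 48 intervals). Zero-length stays are
  accepted.
- Flow-completeness categories are mutually exclusive and exhaustive:
  complete (triage + first + last EWS), ews_no_triage (first EWS, no
  triage), triage_only (triage present, flow otherwise incomplete),
  blackbox_only (neither triage nor first EWS). "Triaged" = complete +
  triage_only.
- An optional timestamp outside [arrival, departure] is blanked with a
  warning; only an unparseable or inverted arrival/departure pair drops a
  record, and every drop is itemised in the validation report.
- LOS truncation clips rather than resamples, placing a small point mass at
  the 1-min and 48-h bounds.
- Problem sizes in the test suite: oracle equivalence on 1,000 randomised
  record sets over 3-day grids; dispersion calibration on 2,000 × 10,000
  Poisson draws; carry-over null calibration on 1,000 synthetic years;
  end-to-end determinism on two-week runs. The full default suite completes
  in well under a minute of CPU beyond the two calibration tests.

## Known limitations

- Patients present before the period start are structurally invisible;
  analyses of periods not preceded by a quiet spell should extend the period
  backwards rather than trust the first day (burn-in only mitigates).
- Boarding (admitted patients waiting for an inpatient bed) is not
  measurable from these timestamps and is out of scope.
- Nurse counts come from the roster, not from realised staffing; sickness,
  ad-hoc transfers and the nurses absorbed by trauma calls are not modelled.
- The exceedance risk is a point estimate; no confidence bands are attached
  to the ECDF.
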