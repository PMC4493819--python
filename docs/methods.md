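# Methods

## Model and assumptions

The package prices an "ideal" life-saving intervention: without it the
person dies within the year (risk `p = 1`, one-year risk duration); with it
they survive (`e = 1`) and rejoin the average morbidity, mortality and
health-cost trajectories of their age cohort. The comparator arm is death
— zero future health, zero future cost — so the survivor's full remaining
discounted streams are the increment. The cohort is propagated through a
deterministic two-state (alive/dead) annual-cycle process from the starting
age to a terminal model age of 105; survival mass beyond the terminal age is
discarded (no forced death probability of 1 at 105). The generalised price
for uncertain death and imperfect effectiveness multiplies the ideal price
by the expected deaths averted per treated person, `p·e`; multi-year risk
durations are a declared extension point and raise an error rather than
silently approximating.

Accrual and discounting conventions, chosen once and used identically by
the closed summations (`emic.model`) and the explicit state machine
(`emic.markov`):

* the reward for the year lived at age `i` accrues if the person is alive
  at the start of that cycle; death happens at the end of a cycle;
* the first cycle is discounted by one full year — exponent `i − k + 1` —
  and there is no half-cycle correction;
* undiscounted life expectancy is the plain sum of the survival curve,
  the same accrual convention with `r = 0` and no morbidity weight.

Mortality improvement is applied to annual death probabilities (not
hazards), multiplicatively along the cohort's calendar diagonal: a person
aged `k` in the base year reaches age `i` in year `base + (i − k)`, and each
calendar year after the base year contributes a factor `1 − reduction`.
The default schedule (2 % per year through 2026, 1 % thereafter, 2011 base)
reflects long-run New Zealand trends; the baseline year itself is never
reduced. Morbidity (pYLD) and cost schedules are held static over calendar
time — projecting them forward the way mortality is projected is a
plausible alternative we deliberately did not take, since there is no
comparably standard trend assumption for them.

Expected per-capita cost composition is
`c(i) = g · [c_bg(i) + m(i) · q̃(i) · c_lyol(i)]`: the decedent
(last-year-of-life) cost is incurred with the year's death probability,
its age-band multipliers (1.1/1.2/1.3 for 65–74/75–84/85+) act only on the
decedent component, and the global under-capture scale `g = 1.2` then
applies to everything. The source adjustments state both factors but not
their order of composition; this ordering is the package's own choice and
is configurable. Because `q̃` is trend-adjusted, the adjusted cost schedule
is specific to a starting age.

## Parameters

| parameter | units | default | why |
|---|---|---|---|
| CET | currency per HALY | 45 000 | GDP-per-capita rule of thumb for NZ 2011 |
| discount rate `r` | per year | 0.03 | standard health-economics base case; 0 and 0.06 as sensitivity |
| risk of death `p` | probability | 1 | ideal life-saving scenario |
| effectiveness `e` | probability | 1 | ideal life-saving scenario |
| risk duration | years | 1 | only supported value |
| terminal age | years | 105 | cohort followed up to 105 |
| global cost scale | — | 1.2 | corrects cost under-capture across all ages |
| LYOL multipliers | — | 1.1/1.2/1.3 | missing residential-care spend at 65–74/75–84/85+ |

Currency is unitless throughout: the threshold and the cost schedules must
share units, which is documented rather than enforced by conversion.

## Numerical choices

All arithmetic is double precision; display rounding (half-up, via decimal
arithmetic) exists only in explicitly requested display copies — whole
thousands for the age table, two decimals of millions for the threshold
grid — so that printed-table comparisons match conventional rounding.
Projected death probabilities are clipped to [0, 1] after trend
multiplication. Negative EMICs (future costs exceed the value of future
health at the threshold) are reported as-is with a flag, never clamped.
The Markov engine is cohort-fraction propagation, not Monte-Carlo
microsimulation: the model is an expectation tool and determinism makes the
cross-check exact to floating-point accumulation order (observed agreement
~1e-15 relative, asserted at 1e-9).

Five-year-group inputs are expanded to single ages as step functions, and
grouped outputs are evaluated at group midpoints (2, 7, …, 92). When a sex
column is present in an input file a single stratum must be selected;
results for both sexes are obtained by running each stratum and combining
externally, since no authoritative aggregation weighting is assumed.

## Synthetic data

The generators emulate the qualitative shape of human inputs so the full
pipeline is testable offline: a Gompertz–Makeham mortality hazard
`h(x) = c + a·e^{bx}` converted by `q = 1 − e^{−h}` (always a valid
probability), a logistic morbidity curve with asymptote below 1, and an
exponentially rising cost curve with an infant bump and a proportional
decedent component. Defaults (`a = 3e-5`, `b = 0.09`, `c = 2e-4`, morbidity
asymptote 0.30 centred at 75, cost floor 1500 growing at 5.5 %/year) are
order-of-magnitude humanlike only — they are not calibrated to any
country's demography, and passing tests on them demonstrates internal
consistency of the machinery, not agreement with real populations. Real
data differ in ways the generators do not attempt: accident humps in young
adult mortality, cohort effects, non-logistic morbidity, cost structure by
service type. Randomized families for the cross-validation suite draw
parameters from wide plausible ranges and add seeded lognormal per-age
hazard noise.

Where raw national inputs are needed but unavailable, the embedded
reference table (`nz2011_reference`) substitutes published New Zealand 2011
HALE and discounted-cost values by five-year age group as *inputs*; the
maximum intervention costs are always recomputed from them, never embedded.
Because those values are printed rounded (one decimal year, whole thousands),
anything derived from them carries that input rounding.

## Known limitations

* Only the one-year risk duration is implemented; `p` and `e` enter as a
  simple `p·e` scaling of the ideal price.
* No equity or age weighting, no currency/PPP conversion, no figure
  rendering beyond emitting plottable tables.
* The reference table's published EMIC column is not internally consistent
  with its own published HALE and cost columns in several rows; this package
  implements the stated formula and recomputes EMIC from each row's inputs
  rather than reproducing that column cell-for-cell. Threshold-grid rows
  that are consistent with their inputs (the youngest and oldest groups)
  reproduce exactly to display precision.
* Problem sizes in the test and acceptance runs — 106-age cohorts, 50
  randomized tables per discount rate, annuity horizons of a few hundred to
  a few thousand cycles — were chosen so each analytic tolerance (1e-9
  relative cross-check agreement, 1e-6 closed-form error) is met with a
  comfortable margin; the model itself has no stochastic component.
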