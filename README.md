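# emic

How much can a health system pay, up front, for an intervention that saves a
life at age *k* while remaining cost-effective? This package computes that
amount — the **estimated maximum intervention cost (EMIC)** — from a
discounted two-state ("Alive"–"Dead") cohort life-table model, for health
economists and policy analysts who want a rapid screening number before
commissioning a full cost-effectiveness analysis.

## The model

The comparator is death: zero future costs, zero future health. A saved
person rejoins the average morbidity, mortality and cost trajectories of
their cohort, so the increment is their entire remaining stream. Requiring
the incremental cost-effectiveness ratio to stay at or below a
cost-effectiveness threshold CET (currency per health-adjusted life-year),

```
ICER = (A + C(k)) / HALY(k) ≤ CET
```

gives the maximum one-off price

```
EMIC = A_max = CET · HALY(k) − C(k)
```

with the expected discounted streams, followed to a terminal model age
(default 105, annual cycles, no half-cycle correction):

```
HALY(k) = Σ_{i=k}^{105} S(i) · (1 − pYLD(i)) / (1+r)^(i−k+1)
C(k)    = Σ_{i=k}^{105} S(i) · c(i)          / (1+r)^(i−k+1)
```

Here `S(i)` is the probability of being alive at the start of the year lived
at age *i* (from the cohort's annual death probabilities, reduced along the
calendar diagonal by a secular mortality trend — for the NZ 2011 baseline,
2 %/year through 2026 and 1 %/year after), `pYLD(i)` is the per-capita
prevalent years lived with disability, and `c(i)` is the expected per-capita
health-system cost, composed as
`c(i) = scale · [c_bg(i) + m(i) · q̃(i) · c_lyol(i)]` with a global scale of
1.2 and last-year-of-life multipliers m(i) of 1.1/1.2/1.3 for ages
65–74/75–84/85+. When death is not certain (risk `p`) and the intervention
not perfect (effectiveness `e`), the price scales by the expected deaths
averted: `EMIC = p·e·(CET·HALY − C)`.

The package ships an explicit alive–dead Markov engine (`emic.markov`) that
re-evaluates the same cohort by state propagation as an independent
cross-check of the closed summations, synthetic Gompertz–Makeham input
generators so everything is testable without external data, and an embedded
table of published New Zealand 2011 HALE and cost values by five-year age
group (`emic.nz2011_reference()`).

## Worked example

A 15–19-year-old (NZ 2011 reference inputs, 3 % discount, CET NZ$45,000):

```
$ emic emic --age 17 --fixture
HALY(17) = 26.20
C(17) = $51,000
EMIC = $1,128,000
```

The survivor gains 26.2 discounted health-adjusted life-years worth
NZ$45,000 each (NZ$1,179,000) and goes on to incur NZ$51,000 of discounted
future health-system costs, so the most a payer can spend on saving them is
NZ$1,128,000. The same surfaces are available as tables:

```
$ emic age-table --fixture --round | head -3
age_group,midpoint,le,hale_0,cost_0,emic_0,hale_3,cost_3,emic_3,hale_6,cost_6,emic_6
0-4,2,88.2,75.8,209.0,3202.0,28.8,42.0,1254.0,16.4,17.0,721.0
5-9,7,82.8,70.7,203.0,2979.0,28.0,43.0,1217.0,16.2,17.0,712.0

$ emic cet-grid --fixture --round | head -2
age_group,20000,30000,40000,50000,60000,70000,80000,90000,100000
0-4,0.53,0.82,1.11,1.4,1.69,1.97,2.26,2.55,2.84
```

`age-table` reports HALE in years and costs/EMIC in thousands of NZ$ per
discount rate (a child's life is worth up to NZ$1.25M at 3 %); `cet-grid`
reports EMIC in millions across willingness-to-pay thresholds. Raw
age-indexed CSV inputs can replace the embedded fixture (`--lifetable`,
`--morbidity`, `--costs`, plus a YAML scenario), and `emic synth` writes a
consistent synthetic input set to experiment with.

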