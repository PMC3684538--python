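# impact2cpr

Service-delivery organisations in family planning usually report commodity
counts or couple-years of protection (CYPs). Neither says how much the
organisation raised the national **modern contraceptive prevalence rate
(CPR)** — the share of women of reproductive age (WRA, 15–49) using a modern
method — because (a) clients of long-acting and permanent methods (LAPMs:
IUDs, implants, sterilisation) keep using them for years after the service
is recorded, and (b) some "new" clients merely switched provider
(*substitution*) and were already counted in the CPR.

`impact2cpr` implements the accounting model that bridges that gap, for
programme analysts and M&E staff of individual service-delivery
organisations. From annual per-method service counts it produces modelled
user numbers and the organisation's annual **percentage-point contribution
to increasing the modern CPR**.

## The model

**Users from services.** Each LAPM provision year spawns a virtual cohort.
IUD/implant cohorts follow cumulative continuation rates (CCRs):

```
users[y+n] = services[y] · (CCR_n + CCR_{n+1}) / 2 ,   n = 0 … D−1,
```

with CCR₀ = 1 and the whole cohort removed at the method's maximum duration
D. Sterilisation cohorts decay by survival only, applied recursively:

```
users[y+n] = users[y+n−1] · (₅pₓ)^{1/5},
```

where ₅pₓ is the model life-table survival probability for the age group
holding the cohort's median age (ageing one year per step, interpolated in
the projected life expectancy e₀ of year y+n), until the cohort's median age
passes 49. Short-term users are `services / units-per-year` (13 pill cycles
= one pill user-year).

**From users to CPR points.** Each trend year, new users are split by the
client profile into adopters, continuers, and provider changers. Continuers
(then adopters, if needed) first fill the gap between surviving cohorts and
the previous year's counted total; only left-over adopters increase the
contribution; provider changers never count. The counted total divided by
that year's (optionally in-union) WRA, minus the baseline-year share, is the
percentage-point contribution to increasing CPR — so population growth
automatically demands extra users just to stand still.

## Worked example

```python
import impact2cpr as icpr

history, assumptions, profile = icpr.toy_example()   # synthetic programme
trend = icpr.run_trend(history, assumptions, profile, 2005, 2011)
print(trend.summary_report())
```

```
Contribution to increasing modern CPR
=====================================
Baseline year: 2004
Baseline users: 314
Baseline CPR contribution: 0.01 percentage points
Trend: 2005-2011 (excluding condom)

  year   total in CPR  pct points  increase
  2005            373        0.01      0.00
  ...
  2011          1,493        0.02      0.02

Cumulative percentage-point increase: 0.02

Results can be read as a contribution to increasing the national modern CPR
only assuming all other providers at least maintain their baseline
contributions.
```

The toy programme serves ~300 modelled users in its 2004 baseline year
(0.01 % of 4.5 million WRA — it is a 1/100-scale example) and ends 2011 with
1,493 users counted in the CPR; the 0.02-point cumulative increase is the
2011 counted share minus the 2004 baseline share. At the generator's full
default scale the same run yields a ≈0.6-point baseline and a ≈1.5-point
cumulative increase.

A command-line interface wraps the same engine:

```bash
impact fixture --out demo/ --seed 1        # synthetic history + assumptions
impact run    --config cfg.yaml            # trend.csv, summary.txt, provenance.json
impact sweep  --config cfg.yaml            # per-scenario tidy CSV
```

## Scope

The package covers the service-statistics → users → CPR-points pipeline
only. Downstream health/demographic/economic outputs (pregnancies averted,
maternal deaths averted, DALYs, cost savings), country default databases,
and survey methodology for client profiles are out of scope. See
`docs/methods.md` for assumptions, defaults, and limitations.
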