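# Methods

## The accounting model

The package models, for a single service-delivery organisation, how annual
per-method service counts translate into (1) modelled contraceptive users
per calendar year and (2) the organisation's percentage-point contribution
to increasing the national modern CPR. It is an accounting model, not a
statistical fit: every output is a deterministic function of the inputs.

### User estimation

*Long-acting methods (IUDs, implants).* Services provided in year *y* form
a cohort traced as `services · mean(CCR_n, CCR_{n+1})` for year offsets
n = 0 … D−1, where CCR_n is the cumulative continuation rate n years after
insertion (CCR₀ = 1) and D the method's maximum duration. Averaging
adjacent CCRs credits mid-year discontinuers with half a year of use. At
n = D the entire cohort is removed; a CCR table supplied without its
terminal entry is padded with 0, consistent with that removal. Mortality is
deliberately **not** applied to these cohorts — discontinuation rates in
practice already absorb it, and applying both would double-count attrition.

*Permanent methods (female/male sterilisation).* The cohort persists until
death or ageing out of the reproductive span. Survival is applied
recursively: each year the previous year's estimate is multiplied by
`(₅pₓ)^{1/5}`, the annualised five-year survival probability for the age
group containing the cohort's median age (starting at the median age of
sterilisation and ageing one year per step). The ₅pₓ value comes from the
assigned model life-table family, linearly interpolated in the female life
expectancy at birth (e₀) projected for that calendar year. The cohort is
removed in the first year its median age would exceed 49 (ages 15–49
inclusive count toward the CPR denominator). For male sterilisation the
protected female partner is the counted user; absent partner-age data the
same median age is used — a known approximation.

*Short-term methods (pills, injectables, condoms).* Users are
`services / units-per-year` (pill: 13 cycles, quarterly injectable: 4
doses, condom: 120 units). A "user" is taken to have full coverage for the
whole year — the conservative reading of commodity data, matching how
population surveys would capture a full-year user. All short-term users are
assumed to discontinue at year end; continuation across years is instead
proxied by the client profile (below).

Condoms are excluded from user estimates and CPR accounting by default
(toggle available): wastage and dual protection make condom commodity data
the least reliable user proxy. User counts stay fractional throughout;
rounding to whole women is a rendering concern only, so the iterative
engine does not accumulate rounding bias.

### The CPR engine

Per trend year (baseline year y₀ = first trend year − 1):

1. **Baseline**: total modelled users in y₀ (all cohorts back to the start
   of the history, earliest 1982) and the baseline contribution
   `users / denominator(y₀)`, the denominator being WRA or in-union WRA.
2. **Pre-existing users**: survivors of LAPM cohorts provided ≤ y₀.
3. **New users**: the year's services converted to first-year users
   (long-acting: `services · mean(CCR₀, CCR₁)`; sterilisation: one year of
   survival; short-term: units division).
4. **Allocation**: with maintenance need
   `max(0, previous counted total − pre-existing − existing)` and the
   client profile's continuer/adopter counts C and A: if C ≥ need, maintain
   = need and all adopters increase (situation 1); if C + A ≤ need,
   everything maintains (situation 2); otherwise adopters top up
   maintenance and the remainder increases (situation 3). Provider changers
   are never allocated. The need is clamped at zero; surplus surviving
   users still count — they were counted the year before.
5. **Counting fraction**: `(maintain + increase) / new users` (0 when there
   are no new users), applied uniformly across methods within the year.
   In situation 1 this formula drops continuers in excess of the need; the
   engine follows it literally and surfaces the dropped count as a
   diagnostic (`dropped_continuers`).
6. **Existing users**: each counted LAPM cohort is the full service-derived
   trajectory scaled by its year's counting fraction (ratio method —
   algebraically identical to re-deriving pseudo-services under the model's
   linear formulas), contributing from offset 1 onward.
7. **Total users in CPR** = pre-existing + existing + maintain + increase;
   this replaces the baseline as the next year's maintenance target.
8. **Percentage points**: total / denominator(year) − baseline
   contribution. Because the denominator grows with WRA, maintaining a
   contribution requires recruiting ahead of population growth.

Trend years with zero services are processed normally (degenerate
situation 2, nothing maintained or increased). A client profile supplied
for a single year is broadcast to all trend years with a logged warning.

### Profile sweeps

`profile_sweep` re-runs the full engine per alternative profile rather than
perturbing intermediate results — correctness over speed at desk scale.
Holding the provider-changer share fixed, the cumulative point increase is
non-decreasing in the adopter share (property-tested): in situation 1 extra
adopters increase directly; in situation 3 the counted total is A + C,
unchanged by the split; transitions between situations preserve the
ordering.

## Defaults and bundled data

* **Method set** (`data/default_methods.yaml` + CCR CSVs): pill 13
  cycles/year and 1/15 CYP per cycle, and 10-year IUD 4.6 CYP, follow the
  published USAID CYP conventions. The CCR tables and the remaining
  units/CYP factors are *illustrative editable defaults* — organisations
  should substitute their current assumption tables. All tables are
  validated at load (CCR₀ = 1, non-increasing, within [0, 1]).
* **Life tables** (`data/life_tables_synthetic.csv`): constructed
  *synthetic* anchor families with the shape of the standard model
  life-table systems (₅pₓ per 5-year age group, ages 15–54, at e₀ anchors
  50/60/70/80), not the published Coale-Demeny/UN tables. The engine only
  needs a (family, e₀, age) → ₅pₓ lookup; users can supply real tables in
  the same CSV format.
* **e₀ lookups** interpolate linearly between supplied calendar years and
  clamp to the nearest endpoint outside them: sterilisation cohort tails
  can outlive any finite projection, where the nearest projected mortality
  level is the only defensible extrapolation. WRA and in-union proportions
  are strict lookups — a missing year is an error naming the year, because
  a CPR denominator cannot be extrapolated silently.
* **Published reference table**
  (`data/madagascar_published_estimates.csv`): the published user-category
  estimates for the Madagascar programme, 2005–2011 (condoms excluded),
  bundled as reference data for consistency checks. The per-method service
  history and country assumption set behind them are not in the public
  record, so these outputs are checked for internal arithmetic consistency
  (subtotals, orderings, the 2011 totals, the users-per-service ratio), not
  recomputed.

## The synthetic-data generator

`FixtureParams` defaults describe a growing sub-Saharan-scale programme:
services growing 35 %/year with 10 % lognormal noise from a mixed-method
base (an eightfold user increase over a seven-year trend), the measured
client profile 22.4 % adopters / 49.2 % continuers / 28.4 % provider
changers applied to all years, 4.5 million WRA growing 2.8 %/year, 70 % in
union, e₀ rising from 62 by 0.3 years/year, all-women CPR basis, history
1996–2011. `toy_example()` is the same shape at 1/100 service scale, with
a committed regression snapshot.

What the generator does *not* emulate: real programmes' year-to-year method
mix shifts, service interruptions, data-quality artefacts (supply-chain
inflation, stock-outs), or year-varying client profiles. Passing tests
therefore demonstrate the accounting engine's correctness and its
qualitative behaviour (continuation gap, substitution discount, population
growth offset), not calibration to any specific country programme.

## Numerical choices

* All arithmetic in float64; engine-vs-reference agreement is asserted to
  1e-9 relative.
* `users_needed_to_maintain` clamps at 0; the counting fraction is defined
  as 0 when there are no new users.
* Interpolations (e₀ in year, ₅pₓ in e₀) are piecewise linear with
  clamping at the range ends.
* Method names in input files are matched case-insensitively through an
  alias table ("IUD-10yr", "Copper T 380A", "depo", …).
* Years are calendar integers; the model has strictly annual resolution.

## Problem sizes

The test suite runs ~150 tests in a few seconds: the engine-vs-reference
equivalence uses 100 random mini-configurations (8-year histories, 4-year
trends, 4 methods), which is ample to exercise every allocation situation,
both CPR bases, and sterilisation/long-acting/short-term interactions. The
acceptance script's synthetic run uses the full default shape (16-year
history, 7-year trend, 8 methods, ~7 million services).

## Known limitations

* The increasing-CPR figure is conditional on all other providers at least
  maintaining their baseline contributions; the model cannot see other
  providers, market exchange of provider changers, or whether departing
  clients continue elsewhere (it conservatively assumes they stop).
* No feedback from contraceptive use to fertility or the WRA projection.
* Method switching toward more effective methods carries no credit in this
  metric; a switcher who also changes provider is excluded entirely.
* The client profile is the dominant uncertainty; sweeps over alternative
  profiles are the built-in sensitivity analysis.
* Short-term continuation is proxied by the continuer share of the client
  profile rather than modelled per method.
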