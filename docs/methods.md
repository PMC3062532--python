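# Methods

## Model

`diascale` is a deterministic cohort projection. For each country, annual
under-5 diarrheal deaths over 2010–2015 are obtained by scaling the 2010
baseline death count, band by age band, with a multiplicative
residual-effectiveness cascade.

**Residual cascade.** An intervention with effectiveness *E* and affected
fraction *A*, moving from baseline coverage *c₀* to coverage *c₁(t)*,
contributes the factor *(1 − E·A·c₁)/(1 − E·A·c₀)*. The denominator removes
the protection already embedded in baseline mortality; the product over
interventions applies each effect only to the residual deaths left by the
others. The formulation has three properties the tests verify directly:
it is order-independent, total averted deaths can never exceed baseline
deaths, and residual mortality is bounded below by *D₀·Π(1 − EᵢAᵢ) > 0*
even at universal coverage. Applying the factors sequentially to a running
residual gives the identical result (equivalence checked to 1e-12).

**Assumptions inherited from the modeling framework.** Lives saved scale
linearly with coverage (no threshold, minimum-coverage, or herd-immunity
effects); absent coverage change, the diarrheal mortality rate is constant
over the 5-year horizon, so the baseline scenario reproduces baseline
deaths every year exactly; effectiveness values are treated as universal
across countries.

**Age bands.** Deaths are distributed over {0, 1–5, 6–11, 12–23, 24–59}
months. ORS acts on 0–59 mo, vitamin A on 6–59 mo, every other intervention
on 1–59 mo. The published burden estimates do not break diarrheal deaths
down by month band, so the default distribution (0.05, 0.25, 0.30, 0.25,
0.15) is a package-level configurable reflecting the concentration of
diarrheal deaths in the post-neonatal period; any per-country distribution
summing to 1 can be supplied in the profiles file.

**Breastfeeding sub-model.** Breastfeeding has no (E, A) pair; instead each
band carries relative risks of diarrhea mortality by practice category —
0–5 mo: exclusive 1.0, predominant 2.28, partial 4.62, none 10.53;
6–23 mo: any breastfeeding 1.0, none 2.28; none beyond 23 mo. Shifting the
practice mix from p⁰ to p¹ multiplies band mortality by
Σₖ p¹ₖ·RRₖ / Σₖ p⁰ₖ·RRₖ. Scenario targets name the exclusive, predominant
and partial categories; "none" is always the residual 1 − Σ(named), which
is why targets are validated to sum ≤ 100% per band.

**Coverage trajectories.** Linear from the 2010 baseline to the 2015
target; a country already at or above a target maintains its achieved rate
(effective target = max(baseline, target)). Coverage is stored in percent
at every file boundary, exactly as published, and converted to proportions
at a single point on entry to the engine. 2010 is both the baseline and the
first projection year, so deaths averted in 2010 are zero by construction.

## Parameters

| intervention | E | A | ages (mo) | ambitious | universal | WASH |
|---|---|---|---|---|---|---|
| ORS | 0.93 | 0.95 | 0–59 | 75 | 90 | |
| zinc | 0.23 | 1.00 | 1–59 | 50 | 90 | |
| antibiotics (dysentery) | 0.99 | 0.05 | 1–59 | 75 | 90 | |
| rotavirus vaccine | 0.74 | 0.39 | 1–59 | 50 | 90 | |
| vitamin A | 0.32 | 1.00 | 6–59 | 90 | 90 | |
| hand-washing | 0.48 | 1.00 | 1–59 | 35 | 55 | ✓ |
| improved sanitation | 0.69 | 1.00 | 1–59 | 67 | 75 | ✓ |
| safe water source | 0.17 | 1.00 | 1–59 | 75 (Africa) / 86 (Asia) | 99 | ✓ |
| home water treatment | 0.21 | 1.00 | 1–59 | 30 | 70 | ✓ |

A for ORS and antibiotics partitions diarrheal deaths into non-dysentery
(95%) and dysentery (5%) exactly; rotavirus acts on the 39% of diarrheal
deaths attributable to rotavirus. The ambitious safe-water target is
region-specific and published only for Africa and Asia; the six Latin
American/Caribbean countries in the cohort (region "Other") follow the Asia
value of 86, a package design choice. Countries flagged not vitamin-A
deficient ("na" in the baseline table) are excluded from the vitamin A
intervention outright — no trajectory, no averted deaths, no cost — rather
than treated as zero coverage. Missing zinc coverage defaults to 0; any
other missing cell is a load error.

## Costing

Ingredients-based: annual cost = population in need × coverage × unit cost,
plus a flat per-country outreach/communication line. Denominators follow
the delivery channel — children under 5 for individual prevention (vitamin
A restricted to the 6–59 mo share, default 0.9), households with under-5
children for WASH (under-5 children ÷ children-per-household, default 1.8,
rounded up), and treatment episodes for case management (episodes per
child-year, default 2.9; antibiotics costed only on the dysentery fraction
of *episodes*, default 0.10 — deliberately distinct from the 5% dysentery
share of *deaths*, since severity differs). Treated episodes scale with
coverage, with "all cases treated" as the 100%-coverage endpoint.
Breastfeeding promotion is costed per child with the exclusive 0–5 mo
prevalence trajectory as its coverage proxy, since promotion programs have
no published coverage indicator of their own.

The published costing drew prices from supply-catalogue and salary
databases that are not reproduced here, so all unit costs are configurable
YAML inputs with synthetic defaults chosen for order-of-magnitude
plausibility (ORS $0.50/episode, zinc $0.40, antibiotics $1.20, vitamin A
$0.60/child-year, rotavirus $5.00, promotion $1.00; WASH per household-year:
water source $20, sanitation $15, treatment $3, hand-washing $2; outreach
$100k/country-year). Absolute cost levels therefore carry no empirical
weight; the structure — WASH vs non-WASH streams, baseline-continuation vs
additional cost, per-capita denominators over total population — is the
modeled content. No discounting, inflation, capital or health-system
strengthening costs; currency is a pass-through label.

## Synthetic data

The generator emulates the structure of the published inputs: per-column
uniform coverage within each intervention's observed 68-country min–max
span, under-5 populations of 0.2–25 million growing 1–3%/yr, diarrheal
mortality of 0.2–4 deaths per 1000 under-5 children per year, a 44/18/6
Africa/Asia/Other region mix, and Dirichlet-sampled breastfeeding mixes.
One integer seed drives all draws through named sub-streams (SHA-256 of the
stream name mixed into the seed sequence), so outputs are byte-identical
across runs and adding a generator does not perturb existing streams.

What it does **not** emulate: cross-country and cross-intervention coverage
correlations, the heavy right tail of the real burden distribution (a few
very large countries carry half the deaths — which is why the synthetic
top-5 share of averted deaths sits near 20–25% rather than ~50%), or any
real country's demography. Passing tests on synthetic cohorts demonstrates
the correctness of the mechanics, not the realism of any headline number.

The known-answer construction inverts the cascade: it places all deaths in
the 6–11 mo band (covered by every intervention), sets the breastfeeding
baseline equal to the scenario's 2015 target state (multiplier exactly 1),
and solves per-intervention baseline coverages so the 2015 reduction
factors multiply to a requested scalar, greedily capping each factor at its
zero-baseline floor. Scalars in (0.1, 1.0] are recoverable under the
ambitious targets; the pipeline reproduces them to 1e-9.

## Numerical choices

- Interpolation uses the convex combination `b·(1−f) + t·f`, which is exact
  at both endpoints and cannot leave [b, t]; a constant trajectory
  (target = baseline) short-circuits to the baseline so unchanged coverage
  yields reduction factors of exactly 1.
- Deaths averted are accumulated per band as `D₀·s_b·(1 − scalar)`, so the
  baseline scenario's averted deaths are exactly 0.0, not merely small.
- Deaths are unrounded floats everywhere inside the engine; rounding
  (deaths to whole persons, per-capita costs to cents, shares to one
  decimal) happens only in the report layer. Cumulative cost rows are sums
  of unrounded yearly values. The proportion-of-baseline series is written
  at full precision because downstream checks recompute scalars from it.
- Country rankings break ties lexicographically by country id; all outputs
  are sorted, making repeated runs byte-identical.
- `E·A·c₀ = 1` (baseline coverage already averting every affected death)
  raises rather than dividing by zero; it cannot occur with the shipped
  parameters.

## Problem sizes

The test suite runs the closed-form equivalence on 1,000 random
single-intervention cases, the cascade property search on 10,000 random
parameter sets, 100 known-answer bundles through the command-line pipeline,
and the full 68-country, three-scenario run twice for bitwise
reproducibility; the whole suite completes in well under a minute. The
acceptance script uses the same 68-country scale with 1,000 closed-form and
20 known-answer verification cases.

## Limitations and extension hooks

- The stunting-mediated indirect effect of WASH interventions on
  non-diarrheal mortality is not modeled (no published effect sizes);
  `project_deaths` exposes an `indirect_wash_multiplier` hook, shipped
  disabled at 1.0.
- Measles vaccination is out of scope: measles-associated diarrheal deaths
  are attributed to measles.
- No equity or reach modeling: the hardest-to-reach children are implicitly
  covered at the same marginal cost and effectiveness as everyone else.
- Diarrheal deaths averted understate the package's full benefit, since
  several interventions also avert deaths from other causes; accordingly no
  cost-per-life-saved metric is computed.
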