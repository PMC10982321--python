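# Methods

## The decision problem

Refractory angina patients with no revascularization option cycle through
hospitalizations, emergency-department (ED) admissions, coronarographies,
outpatient visits and elective PCI at high annual rates. The coronary sinus
reducer is a one-off implanted device (€7,000 plus the implant admission)
that, in responders, cuts those rates sharply. Two standard
health-technology-assessment questions follow, and this package answers both
from one parameter set:

* **Affordability (BIA).** What does the payer spend, year by year, if
  device uptake rises versus stays flat?
* **Efficiency (CUA).** What does a QALY gained through implantation cost
  relative to continuing standard of care?

## Budget-impact model

The eligible population comes from a stepwise funnel: a base population
(6,795,374 Italians aged 65–74 in the packaged defaults), an angina-pectoris
prevalence stage, a 12% refractory fraction and a 60% eligibility fraction,
giving 17,696 patients. Each stage count is rounded half-up to whole persons
— the convention that reproduces the published 29,493 and 17,696 exactly.
The prevalence stage is stored as the exact ratio 245,771/6,795,374 so the
funnel reproduces the published intermediate count rather than a re-derived
prevalence estimate.

Each scenario assigns the pool to arms by a linear device-share trajectory
share(y) = share(1) + (y−1)·increment, kept at full precision (the
comparator share is exactly the complement). Per-patient annual cost is
Σ rate·tariff over the five HRU drivers plus the usage-weighted drug basket,
plus the implant tariff in a reducer patient's first year. Patients newly
captured by a rising share in year *y* are implants that year; carried-over
reducer patients pay the steady-state reducer cost. With nonzero mortality,
survivors of the previous reducer cohort are n(y−1)·(1−m) and new implants
make up the difference. Headcounts stay fractional (expected values); only
the funnel is integer.

The BIA is **undiscounted by default** (the usual budget-impact convention;
discounting belongs to the CUA) with a `discounted=True` escape hatch.

Two inputs of the published analysis were never printed: the annual incident
eligible cohort and the annual mortality of the pool. Both are first-class
parameters (`annual_incident_eligible`, `annual_mortality`) so the
sensitivity analyses can vary them, and both default to 0 — a constant
prevalent pool. Consequently the packaged defaults do **not** reproduce the
published absolute totals (€649M-scale), the €59,772 cumulative saving or
the published avoided-event counts, and the package makes no attempt to:
with the printed tariffs and rates the reducer arm is already cheaper than
SoC in year 1 (€10,409 vs. €11,040 per patient), so the uptake scenario
saves from the first year, whereas the published pattern (extra cost in
years 1–2) implies additional unprinted structure. The published
differential figures are themselves mutually inconsistent (€59,772.44 in the
results, €64,939.04 implied by the two printed totals, €39,644.27 in the
conclusion), which reinforces treating them as out of scope. Likewise the
drug-cost table contains an internal conflict (a €27.9 beta-blocker cell,
and a ranolazine daily cost inconsistent with its annual cost); the packaged
defaults use the component annual costs from the running text, the only set
that reproduces the €386.44 weighted total.

Post-implant therapy de-escalation is deliberately **not** credited in the
base case (`drug_reduction_on_reducer = 0`), matching the source's
conservative choice; the field exists because the tornado analysis names it
as a lever.

## Cost–utility model

A decision tree, not a Markov model: the reducer cohort splits once into
responders (probability `p_success`) and non-responders, then each arm walks
yearly alive/dead states. Per alive patient-year the reducer arm accrues the
mixture utility p·u₊ + (1−p)·u₀ and the SoC arm u₀; death accrues nothing.
Costs: the reducer arm pays an implant-inclusive first-year cost
(€15,702/patient), then responders pay the steady-state reducer cost and
non-responders the SoC cost; the SoC arm pays €6,988/patient/year
throughout. Effectiveness is constant over the horizon (no decay), per the
long-term follow-up evidence the source adopts. Both costs and QALYs are
discounted at 3.5%/year with the first model year undiscounted
(factor 1/(1.035)^(y−1)); a `first_year_discounted` flag flips the
convention. No half-cycle correction — the model is plain yearly accounting.

Two tree defaults are **inferences, not published values**, and are flagged
as such: `p_success = 0.9451`, solved from the published year-1 reducer-arm
cohort QALY total (5,864.285/10,000 per patient) via
p = (q̄ − u₀)/(u₊ − u₀) assuming no first-year deaths; and
`annual_cost_reducer_later = €2,550/patient/year`, solved from the
year-1→2 step of the published reducer cost cumulatives. Both are ordinary
overridable parameters.

The published per-horizon table is *not* reproduced beyond year 1: its SoC
QALY cells imply an unstated survival/discount schedule (e.g. a year-1 SoC
cohort QALY of 4,389.2 where 10,000 × 0.456 = 4,560) that cannot be
recovered from the text. What the package does guarantee — and tests — is
the table's internal arithmetic: increments recomputed from the cumulative
cells, the ICER as their ratio, and the sign logic of the verdict.

**Verdicts.** "dominant" = no more expensive and strictly more effective
(including strictly cheaper at equal effectiveness), "dominated" = the
mirror case, "equivalent" = both increments zero; otherwise the ICER is the
ratio. The ΔQ = 0 edge cases are classified by the cost sign rather than
reported as ±∞ ratios.

## Sensitivity analyses

**Tornado (one-way DSA).** A named registry maps each lever (responder
percentage, PCI rate, SoC hospitalization and coronarography rates, ED rate,
mortality, drug-therapy reduction, visit rate) to one or more parameter-set
paths; rates shared by both arms move together. Each entry recomputes the
full target — the cumulative BIA differential or the 5-year cost-per-QALY
ratio — at base·(1±δ), δ = 0.15 by default, everything else held at base;
entries sort by swing. Parameters whose base value is 0 (mortality, drug
reduction in the base case) are unmoved by a relative perturbation and show
zero swing; the published qualitative ordering of the tornado is therefore
not asserted, since it presumes unpublished nonzero bases.

**PSA.** Each of 1,000 draws (default) independently samples the tree
parameters — probabilities and utilities from beta distributions
parameterized by the method of moments (shape1 = m·k, shape2 = (1−m)·k with
k = m(1−m)/v − 1 and v = (0.15·m)²), cost magnitudes from normals truncated
at zero — reruns the 5-year CUA, and records (ΔC, ΔQ). No correlation
structure is imposed (none was specified). Draw order follows the registry
order with a single seeded generator, so runs are bit-reproducible within
this implementation. Beta draws are clipped to the open unit interval at
machine precision: a responder probability near 1 at 15% relative SD is
heavily skewed and can otherwise round to exactly 1.0 in floating point.
Probabilities sitting exactly on {0, 1} (e.g. the default survival of 1)
have no feasible beta variance and are held as point masses rather than
failing the run. The CEAC reports P(λ·ΔQ − ΔC ≥ 0) on a willingness-to-pay
grid of €0–100,000/QALY in €1,000 steps (the Italian reference band is
€30,000–40,000/QALY); ICERs are left undefined (not ±∞) for ΔQ = 0 draws and
never enter the quadrant or CEAC logic.

## Synthetic cohorts

The aggregate inputs (rates per patient-year, mean utilities, annual
mortality) were measured on an observational cohort that is not deposited;
the generator produces patient-level stand-ins with exactly the structure
those aggregates assume: event counts Poisson(rate × exposure-years) — the
minimal model consistent with a "per patient per year" summary; utilities
beta around the arm mean (the responder-mixture mean in the reducer arm) at
15% relative SD; death geometric per year, censored administratively at the
end of follow-up, on the model's yearly grid. Deliberately *not* emulated:
overdispersion/within-patient correlation of event counts, utility decay,
angina-class trajectories, non-uniform censoring, placebo effects. Passing
recovery tests therefore show the pipeline is self-consistent under its own
assumptions, not that real registry data meet them.

Estimation inverts the generator: rates = total events / total patient-years
at risk, utilities = sample means, mortality = pooled discrete-time
life-table hazard (the year of death counts as a year at risk). The
Kaplan–Meier routine wraps `lifelines.KaplanMeierFitter` on the yearly grid
and is checked against a brute-force empirical-survival oracle in the
uncensored case. `rebuild_parameter_set` maps estimates back onto a template
parameter set; the responder utility is solved from the reducer arm's
mixture mean using the template's responder probability, since patient-level
utilities alone cannot separate the responder fraction from the responder
utility.

## Numerical conventions and problem sizes

Fractions internally, percent only at the reporting edge; EUR at full
precision internally, two decimals at display. Funnel rounding is half-up.
YAML round trips are lossless (floats serialized via shortest-roundtrip
repr). Test problem sizes: 50,000-patient cohorts for 3-standard-error rate
recovery, 100 replicates of 20,000 patients per arm for verdict recovery,
10,000 Monte Carlo draws for the PSA-consistency check — sizes at which the
binomial/Poisson error bands are decisive while the full suite stays in the
tens of seconds.

## Known limitations

* The BIA treats headcounts as expected values, not integer patients.
* Implant-cost timing assumes arm switching only via net share growth;
  churn between arms at constant share is not modelled.
* The CUA tree has no morbidity states (no angina-class transitions) and no
  effectiveness decay; dominance verdicts therefore persist once reached
  under full survival.
* PSA parameters are independent; correlated utilities/costs would widen or
  narrow the cost-effectiveness cloud in ways the model cannot show.
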