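# Methods

## Model

`matcea` implements a decision-tree cohort model of a single pregnancy
through delivery. The cohort (default 10,000 women) is split, in
expectation, across eight cells: ANC attendance × delivery location
(health facility / home) × essential obstetric care (EOC) access. Within
each cell a woman experiences exactly one of five mutually exclusive
delivery outcomes — post-partum haemorrhage (PPH), sepsis, hypertensive
disorders (HTD), obstructed labour (OL), or an uncomplicated delivery —
followed by death and sequela resolution. All arithmetic is on expected
real-valued counts; every stage conserves the cohort total to 1e-9 and
the engine is exactly linear in cohort size.

Care effects enter at three points:

* **Incidence.** PPH and OL incidence is independent of care. Sepsis
  incidence is multiplied by a hospital relative risk (0.54) for facility
  deliveries. HTD incidence is multiplied by a prophylaxis relative risk
  (0.41) for the covered fraction of ANC attendees (full coverage in the
  insured scenario).
* **Case fatality.** PPH death probability is multiplied by 0.34 under
  EOC; OL death occurs only without EOC; sepsis and HTD case fatality are
  not further modified by EOC (their benefit flows through incidence and
  prophylaxis respectively). These readings are the only ones that
  reconcile the published per-stratum death counts.
* **Sequelae** arise among survivors only: anaemia after PPH (halved
  under EOC), secondary infertility after sepsis, fistula after OL
  without EOC. Surviving HTD cases are tracked for the extended-morbidity
  weight described below.

## Parameters

All inputs live in `src/matcea/data/params_table1.yaml` and are sampled
as declared: beta by mean/sd via method of moments, uniform by min/max,
triangular by mean/min/max with mode = 3·mean − min − max. Point
estimates are distribution means (uniform midpoint, triangular mean).
Two edge cases:

* The anaemia DALY triangular ("0.09 (0.08–0.09)") is infeasible as a
  mean-parameterization — the derived mode (0.10) exceeds the maximum
  because the printed mean is rounded. The shipped entry pins the mode at
  0.09 explicitly (true mean 0.0867).
* The facility/home split for ANC attendees (0.96 / 0.05) sums to 1.01
  and is renormalized to sum to one, preserving the ratio.

Relative risks declared as beta distributions are sampled on [0, 1];
probabilities produced by multiplying a probability and a relative risk
are clamped to [0, 1] (pathological draws are effectively impossible with
the shipped inputs but the guard is validated).

### Calibrated structural defaults

The exact tree structure for the no-ANC stratum is not published; five
structural quantities are therefore **calibrated reconstructions**, fitted
once analytically to the published cohort table and then frozen in the
shipped configuration:

| quantity | default | fitted to |
|---|---|---|
| SoC no-ANC facility share | 0.03859 | EOC fraction of complicated deliveries, 125/751 |
| KSHI no-ANC facility share | 0.07696 | 65/321 |
| KSHI ANC-stratum facility share | 0.97383 | 1,297/1,327 |
| sepsis calibration ratio | 1.11218 | SoC no-ANC sepsis count 65/3,500 |
| SoC HTD-prophylaxis coverage | 0.29910 | SoC ANC HTD count 455/6,500 |

The sepsis ratio scales the declared sepsis rate (mean 0.017) into the
base no-hospital rate (0.01891): the declared mean cannot reproduce the
published subgroup counts under any pure facility-mix reading (the no-ANC
rate alone is 65/3,500 = 0.0186 > 0.017). The hospital relative risk is
applied to facility deliveries, as its name states; with it the published
sepsis cells are matched to within about one case. During PSA the ratio
is held fixed so the declared sepsis distribution drives the uncertainty
multiplicatively.

## Health accounting

Deaths are valued at 23.43 discounted DALYs (a ≈40.5-year residual life
expectancy at 3%/year, computed by the closed form
`(1 − e^(−rL))/r`), sequelae at their per-event weights (anaemia 0.087,
infertility 0.1, fistula 10.93). Two accounting modes exist:

* **loss** — total DALYs incurred (YLL + YLD); used by all invariant and
  microsimulation-equivalence tests.
* **ledger** (default) — each woman is credited a baseline of discounted
  healthy life-years and losses are subtracted, reproducing the scale of
  the published per-scenario "total DALYs" column. Both modes give
  identical scenario *differences*, so the ICER is mode-independent up to
  sign convention.

The published DALY column cannot be derived from the per-event weights
alone: the between-scenario difference (7,724 DALYs) far exceeds deaths
averted × 23.43 plus the printed sequela weights (≈1,300). The residual
is attributed to long-term morbidity among surviving HTD cases — the only
complication whose caseload differs enough between scenarios — via an
**extended-HTD sequela weight**, calibrated analytically so the
point-estimate ledger difference equals 7,724: 21.332 DALYs per surviving
case, with the ledger baseline 38.133 healthy life-years per woman fitted
to the absolute column values (362,581 / 370,305). Both constants are
reconstructions, not published inputs, and the resulting ICER (45.4 at
point estimates vs the published 46.4) inherits that caveat. When an
analysis varies the discount rate, the long-horizon weights (death,
extended HTD, baseline) are rescaled through the closed-form discounting
at the implied ≈40.5-year horizon; the short-duration sequela weights are
left untouched.

## Costs

Provider perspective, US$ 2012. ANC attendees incur the per-pregnancy ANC
cost (mean 36.95); facility deliveries incur the uncomplicated unit cost
(18.43) unless complicated with EOC access, in which case the complicated
package (50.0) applies; complicated deliveries without EOC incur the
uncomplicated cost in a facility and nothing at home; home deliveries
without provider contact are uncosted. Fistula (286.8) and anaemia (11.8)
treatment costs follow cases; they are treated as incurred in year 0 (no
further discounting). The insured scenario adds the annualised
above-service program cost of US$ 24.1 per enrolee across the whole
cohort (US$ 241,000). Under these rules the point-estimate totals are
406,363 (SoC, +2.2% against the published 397,618 — the residual sits in
the unpublished component accounting) and 757,231 (KSHI, +0.2% against
755,690).

## Cost-effectiveness analysis

The deterministic ICER divides the incremental cost by DALYs averted;
quadrant handling: cheaper-and-at-least-as-effective is cost-saving
("CS"), costlier-and-less-effective is dominated, a zero effect
difference with nonzero cost yields an undefined-ratio flag rather than
an exception. The PSA draws every distribution once per iteration and
evaluates both scenarios on the same draw (common random numbers).
Per-draw ratios are summarised by median and 2.5/97.5 percentiles with
cost-saving draws ordered below the smallest ratio and dominated draws
above the largest. The CEAC counts a draw as cost-effective at threshold
w iff it is cost-saving or has a positive health gain with ratio ≤ w —
a rule that is monotone in w by construction and consistent with the
net-monetary-benefit ordering (asserted in tests).

One-way sensitivity analysis varies one parameter at a time to its outer
bounds — distribution support for uniforms/triangulars, mean ± 1.96 sd
truncated to [0, 1] for betas, declared bounds for point entries (± 50%
for the above-service cost, 0–6% for the discount rate, both design
choices) — and ranks parameters by the absolute ICER swing. Under the
calibrated DALY reconstruction the HTD incidence dominates the swing
ranking and every one-way ICER stays far below the WTP threshold; the
sepsis case-fatality swing is structurally small here (its only channel
is ≈6.6 deaths of difference), which is a known divergence from the
published sensitivity ranking attributable to the unpublished morbidity
structure.

Alternative base cases: `soc1` raises SoC utilization to insured levels;
`soc2` raises SoC provider costs to approximate literature
(public-sector) values (ANC 65, uncomplicated 25, complicated 75 — round
reconstructions, not published numbers) and sets quality indicators to
their high bounds; `soc3` combines both. At point estimates the insured
scenario remains very cost-effective against `soc1`/`soc2` and becomes
cost-saving against `soc3`, matching the published qualitative pattern;
the exact alternative-row figures are only approximated.

## Budget impact

Five-year projection of `population in need × per-woman program cost ×
coverage − current expenditure`, at coverage 60/80/100%, with compound
population growth and compound inflation (12.33%/year) for pre-2012
prices. Per-woman costs come from the same cohort engine. The
demographic denominators are **not** published: the defaults (95,000
women in need, growth 2.6%/year, current utilization 0.5) are documented
placeholders, so the published state-wide dollar figure is not
reproducible from the package alone; the projection is validated through
its structural properties (linearity in population, monotonicity in
coverage, zero increment at the status quo).

## Microsimulation

`simulate_individuals` draws one record per pregnancy by sequential
Bernoulli/categorical sampling in a fixed documented order (ANC, visit
count 3–5, location, EOC, prophylaxis, complication, death, sequela) from
a single seeded stream, and prices each record under exactly the cohort
rules, so summed record accounting equals the accounting layer run on the
aggregated table to float precision. The synthetic records emulate the
*structure* of insurance-claims data (one row per pregnancy, care path,
outcome, cost) but none of its real-world messiness — no missingness,
miscoding, repeat visits or within-facility correlation — so agreement
between simulator and expectation engine validates the model's internal
consistency, not its fit to real claims.

## Problem sizes and numerics

Default analyses use the cohort of 10,000, PSA with 10,000 iterations
(about 3 s per replicate), and microsimulation cross-checks at n =
200,000 (3 binomial SEs per table cell). Expected-count arithmetic is
exact double precision; printed-table comparisons round half away from
zero only at the end. Seeded `numpy.random.Generator` streams make every
analysis reproducible; parameter draws traverse keys in sorted order so
the draw is independent of insertion order.

## Known limitations

* The extended-HTD weight, ledger baseline, facility shares, sepsis
  ratio and SoC prophylaxis coverage are calibrated reconstructions of an
  unpublished model appendix; quantities that flow through them (the
  absolute DALY ledger, the ICER denominator, the sensitivity ranking of
  sepsis case fatality) carry that uncertainty.
* No within-pregnancy time dynamics, neonatal pathway, repeat
  pregnancies, patient/societal costs, or health-system capacity
  constraints.
* The budget projection requires externally supplied demography and
  expenditure to be meaningful in absolute terms.
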