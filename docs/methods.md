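# Methods

## Model structure

The cohort enters alive without cardiovascular disease (CVD) at age 60.6
with LDL-C 3.13 mmol/L on high-intensity statins, and is propagated in
1-year cycles over a 30-year horizon through 11 mutually exclusive states:

```
NoCVD → {MI year-1, IS year-1} → {post-MI, post-IS}
      → {MI≥2 year-1, IS≥2 year-1} → {post-MI≥2, post-IS≥2}
all alive states → CV death | non-CV death (absorbing)
```

Year-1 states are tunnels: they are occupied for exactly one cycle (to give
the first post-event year its own costs, utilities and risks) and then
drain into the corresponding long-term state unless a new event or death
intervenes. At most one CV event occurs per cycle. Recurrence counters are
per event type: a patient in the stroke pathway who suffers a first MI
moves to the MI year-1 tunnel, and vice versa, keeping the state count at
11. Revascularization is an expected-event overlay on alive person-time
(procedure cost plus a one-off disutility), never a state.

## Transition probabilities

Baseline first-event rates (nonfatal MI 0.9, nonfatal IS 0.4,
revascularization 1.2 per 100 patient-years in a statin-treated cohort) are
first calibrated to the modelled cohort by
`r_a = r_0 · HR_age^Δage · RR^ΔLDL_pop`. The age hazard ratio is not
published for this model family, so the default is `HR_age = 1` with the
reference age equal to the cohort's own mean age — the calibration is the
identity in the base case and both knobs are config-overridable. Event
rates are then held constant over the horizon (background mortality, not
event-rate escalation, carries the age effect); this is configurable
through the same calibration fields.

On treatment, rates scale as `r_tx = r_0 · RR^ΔLDL` with rate ratios per
1 mmol/L LDL-C reduction of 0.74 (MI), 0.80 (IS), 0.76 (revascularization)
and 0.86 (vascular death). History multipliers apply by source state:
recurrent MI 1.13 from post-MI, recurrent IS 1.13 from post-IS, 1.19/1.36
for ≥2 MI/IS from the respective post-≥2 states, and 1.50 ("any CV event in
the past year") on both event rates from any year-1 tunnel, stacked
multiplicatively with the history multiplier. This is the most literal
reading of the published multiplier labels; the original build's exact
mapping is not published, which is one reason absolute reproduction is not
claimed. The 1.50 multiplier is not applied to CV death; instead CV death
in the first post-event year carries its own relative risk of 1.31.

Background mortality comes from an age-indexed life table (all-cause and CV
rates per person-year, floor-age lookup, last row reused beyond the table).
Non-CV mortality is all-cause minus CV and is treatment-invariant; CV
mortality is scaled by `0.86^ΔLDL`. The rate ratio for any death (0.90) and
for any major vascular event (0.78) are carried as inputs — the former only
in the uncertainty registry, the latter only in the baseline calibration —
and neither affects the base case.

Rates convert to per-cycle probabilities by `P = 1 − exp(−r·t)`. Competing
exits from a state (MI, IS, CV death, non-CV death) are resolved jointly:
total exit probability `1 − exp(−t·Σr)`, apportioned in proportion to the
rates. This is the standard constant-rate multistate treatment; it reduces
to the single-cause formula when one cause dominates and guarantees
row-stochastic matrices without truncation.

## Costs, utilities, discounting

Direct medical costs (2024 USD): annual statin cost 846.1 on all alive
person-time in every arm; PCSK9 drug cost = per-pen price × pens per
administration × administrations per year (26 for Q2W, 13 for Q4W, ≈8.696
for Q6W; inclisiran 3 loading doses in year 1, 2/year thereafter; higher
doses priced as pen multiples of the marketed pen); first-year and
subsequent annual MI/IS state costs; a one-off CV-death cost on the mass
entering CV death each cycle; revascularization cost on expected overlay
events. Non-CV death is cost-free. Utilities are EQ-5D state values with an
annual injection disutility (−0.0003) on injectable arms and a one-off
revascularization disutility (−0.007). The injection disutility is a single
published value and is applied per year regardless of injection frequency;
scaling it with injection count would slightly favour inclisiran and is
left to the config.

Both streams are discounted at 5%/year. Half-cycle correction is
trapezoidal: state payoffs accrue on the average of start- and end-of-cycle
occupancy at the cycle-start discount factor, while one-off event payoffs
(CV death, revascularization) are discounted mid-cycle. The correction is a
single boolean in the cohort settings.

## Comparative analysis

ICURs are computed from unrounded totals. (Published tables in this
literature often round ΔCost and ΔQALY before printing but divide unrounded
internals; dividing the rounded headline increments 11,109.27/0.42 gives
26,450.64, not the printed 26,217.47 — the package always divides full
precision.) The frontier removes strictly dominated strategies (costlier,
no more QALYs), then iteratively removes extended dominance until
incremental ratios are non-decreasing along the frontier. Pairwise ICURs
versus the comparator are reported for every strategy regardless of
dominance status.

## Uncertainty

*One-way:* each parameter in the uncertainty registry moves to its 95%
bounds (discount rate over 0–8%, jointly for costs and outcomes; unranged
costs ±20%), the deterministic pipeline reruns, and the pairwise ICUR is
recorded. Bounds that leave the target dominated are flagged rather than
reported as negative ICURs.

*Probabilistic:* 1,000 independent joint draws — gamma for costs (and
disutility magnitudes), lognormal for risk ratios, normal for LDL-C
reductions, beta for utilities; fixed parameters (event rates, cohort
settings, statin cost) never vary. Distributions are moment-fit: mean =
base value, SD = (high − low)/3.92, except the lognormal whose median is
the base value with σ = (ln high − ln low)/3.92. Parameters are sampled
independently (no published correlation structure). Per-agent pen prices
are drawn once and applied to all of that agent's regimens. CEACs use the
highest-net-monetary-benefit rule on a grid from 0 to 3× GDP plus the two
named thresholds; ties break to the cheaper strategy.

*Scenarios:* the pipeline reruns truncated at 5–30-year horizons.

*Price threshold:* lifetime cost is exactly affine in the per-pen price
while QALYs are price-invariant, so the price at which the pairwise ICUR
equals the WTP has the closed form
`p* = p0 + (WTP·ΔQALY − ΔCost(p0)) / W`, where `W` is the discounted
administration weight (the drug-cost component divided by the current
price). A bisection on the full pipeline is kept as an independent solver
and agrees to 1e−6 relative in the test suite.

## Synthetic life table

The yearbook mortality table used by the original analysis has no public
accession, so the default background mortality is a Gompertz–Makeham
hazard, `all_cause(age) = 0.001 + 2e−5·exp(0.095·age)` over ages 40–100,
with a CV share of deaths rising linearly from 20% at 40 to 45% at 100.
This reproduces the structural features the model relies on — smoothly
increasing mortality, CV fraction below one and rising with age, 60-year-old
all-cause mortality within a factor of two of published East-Asian rates —
but not any country's actual values. Consequences worth being explicit
about: absolute costs, QALYs, ICURs and cost-effectiveness probabilities
computed from the packaged base case characterize the model under this
synthetic table, not any national setting: a table with a higher CV share
of deaths — the channel through which LDL-C lowering saves lives — yields
larger QALY gains and materially lower ICURs for every active regimen.
All qualitative findings are table-invariant in our testing:
the identity and ordering of the frontier, dominance of all other
regimens, monotone ICUR decline with horizon, and the tornado's leading
drivers (discount rate, target drug price, vascular-death rate ratio).
Passing tests therefore certify the machinery and its invariants, not
agreement with any specific national estimate; substituting a real life
table through the CSV interface is the supported path to setting-specific
numbers.

## Numerical choices and problem sizes

- Probabilities and occupancy rows are validated to 1e−12/1e−10; the
  degenerate no-event configuration matches the closed-form annuity to
  1e−10 relative.
- Life-table lookups floor fractional ages; rows beyond the table reuse the
  last row (the default table covers the whole horizon).
- Sampled LDL-C reductions truncate at 0 and sampled rate ratios cap at 1;
  under the registered ranges both events have negligible probability, and
  they keep every draw inside the type invariants.
- PSA uses 1,000 draws (per-seed child seeds below 2^31); the test suite
  uses 40–50-draw PSAs and 10^4-draw vectorized moment checks, sized to
  keep the default run under a few minutes on one CPU.
- Frontier ties (identical cost and QALY) break lexically; zero QALY
  differences are reported as incomparable rather than infinite ICURs.

## Limitations

Full adherence and constant treatment effect over the horizon; no
microsimulation mode; no treatment discontinuation; independence of PSA
draws; the history-multiplier mapping and half-cycle convention are
documented choices where the original build's conventions are unpublished;
and the synthetic life table, as above. The network meta-analysis behind
the LDL-C reductions is taken as input, never re-estimated.
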