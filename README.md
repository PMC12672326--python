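# pcsk9cua

A Markov cohort cost-utility model of PCSK9-inhibitor dosing regimens added
to statin therapy in adults with hypercholesterolemia or at high
cardiovascular risk, from a healthcare-system perspective. It is written
for health-economics analysts who want a tested, scriptable alternative to
spreadsheet/TreeAge builds of this model family: every step — transition
probabilities, cohort trace, discounted outcomes, dominance, sensitivity
analyses, value-based pricing — is an importable, unit-tested function.

## The model

An 11-state cohort state-transition model with 1-year cycles over a
30-year horizon. States: alive without CVD; first-year and long-term states
for first and recurrent myocardial infarction (MI) and ischemic stroke
(IS); and two absorbing states, cardiovascular (CV) and non-CV death.
Revascularization is a cost/disutility overlay, not a state, and at most
one CV event occurs per cycle.

Treatment effects are anchored on LDL-C. Each regimen's absolute LDL-C
reduction ΔLDL (mmol/L, from a network meta-analysis) scales event rates
through rate ratios per 1 mmol/L:

- baseline calibration: `r_a = r_0 · HR_age^Δage · RR^ΔLDL_pop`
- on-treatment rate:    `r_tx = r_0 · RR^ΔLDL`
- probability per cycle: `P = 1 − exp(−r·t)`

with post-event history multipliers (recurrent MI/IS, ≥2 events, any event
in the past year) and a CV-death relative risk of 1.31 in the first year
after an event. Competing exits within a cycle share the joint exit
probability `1 − exp(−Σr)` in proportion to their rates, so every
transition row is stochastic by construction. Costs (2024 USD) and QALYs
are discounted at 5%/year with half-cycle correction; strategies are
compared by the incremental cost-utility ratio ICUR = ΔCost/ΔQALY against
willingness-to-pay thresholds of 1–3× per-capita GDP
($13,291.7–$39,875.0/QALY), with strict and extended dominance removed
along the cost-effectiveness frontier.

Because the national age-specific mortality table behind the original
analysis is not redistributable, the packaged base case uses a synthetic
Gompertz–Makeham life table with an age-increasing CV death share
(`pcsk9cua.synthetic`). A real life table drops in through a 3-column CSV
(`age, all_cause_rate, cv_rate`); absolute results shift accordingly (see
`docs/methods.md`).

## Worked example

```python
from pcsk9cua import base_case, evaluate_all, frontier

params = base_case()
res = frontier(evaluate_all(params), "Statins alone")
print(res.to_frame("Statins alone").round(2).to_string(index=False))
```

prints (synthetic life table):

```
              strategy  total_cost  total_qaly  delta_cost  delta_qaly  icur_vs_reference  icur_frontier    status
         Statins alone    17153.78       12.92        0.00        0.00                NaN            NaN  frontier
 Evolocumab 140 mg Q2W    29264.67       13.12    12110.89        0.20           60308.48       60308.48  frontier
Tafolecimab 150 mg Q2W    29621.65       13.08    12467.87        0.17           73762.62            NaN dominated
  Alirocumab 75 mg Q2W    29973.16       13.07    12819.38        0.16           82002.63            NaN dominated
...
 Inclisiran 300 mg Q6M    55007.26       13.06    37853.49        0.15          258106.46            NaN dominated
```

Statins alone is cheapest; evolocumab 140 mg Q2W is the only non-dominated
active regimen — it buys 0.20 extra QALYs for $12,110.89, an ICUR of
$60,308.48/QALY. All other regimens cost more and deliver fewer QALYs than
evolocumab 140 mg Q2W (dominated); inclisiran is the least favourable.
Under this synthetic mortality table no regimen falls below the 3×-GDP
threshold at current prices; the price-threshold analysis
(`analysis/05_price_threshold.py`) reports, e.g., a maximum cost-effective
evolocumab price of $27.89/pen (−29.2%).

The numbered scripts under `analysis/` run the full study: base case,
tornado, PSA + CEAC, horizon scenarios, price thresholds; each writes CSV
tables into `results/`. The same analyses are available from the shell via
the `pcsk9cua` CLI (`pcsk9cua base-case`, `pcsk9cua psa --n 1000 --seed 1`,
`pcsk9cua price-threshold --wtp 39875`, ...), including with your own
`--params`/`--life-table` files.

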