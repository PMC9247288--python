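# Methods

## Model structure and assumptions

`conflictsim` treats a woman's age at marriage *M* as the single decision
variable of a deterministic life-history model. The assumed causal setting is
a patrilocal, patrilineal agricultural society: marriage age proxies the
bride's accumulated "maternal capital" (education, autonomy, physical
maturity), which shapes her fertility schedule and her children's survival.
The model is population-level and closed-form — no individuals, no birth
events, no stochasticity. Every output is a pure function of *M* and a
parameter set.

Assumptions worth stating explicitly:

- First birth follows marriage by a fixed lag (1 y); reproduction stops at
  35 y. Total fertility is continuous (offspring need not be whole numbers) —
  it is an expected count, not a sampled one.
- Each child is simply alive or dead at age 5; no age pattern of mortality is
  modelled. Mortality is the product of a low-birth-weight pathway and a
  post-natal care pathway, both linear in *M*.
- Stunting is proportional to low-birth-weight risk (catch-up factor 0.75);
  it feeds no other quantity, serving as a health indicator read off at the
  optima.
- Paternity uncertainty rises linearly with *M* (larger social networks,
  greater autonomy); "lost" paternity goes to unrelated men. Fathers carry
  every maternal fitness cost (no remarriage after a wife's death), so
  paternal LRF is the maternal value times (1 − PU).
- In the optional maternal-mortality extension, the per-career risk declines
  cubically with *M* and multiplies maternal fitness once (not per birth).

## Parameters

Defaults in `ModelParameters` (all ramps anchored at the 15 y reference age):

| parameter | default | units | meaning |
|---|---|---|---|
| `reproductive_end_age` | 35 | y | reproductive cessation |
| `first_birth_lag` | 1 | y | AFP − M |
| `ibi_intercept` / `ibi_slope` | 2.0 / 0.25 | y, y/y | inter-birth interval ramp (2 y at 15 → 3.25 y at 20) |
| `lbw_intercept` / `lbw_slope` | 0.9 / 0.1 | –, 1/y | low-birth-weight ramp (0.9 → 0.4 over 15–20) |
| `postnatal_intercept` / `postnatal_slope` | 0.7 / 0.065 | –, 1/y | post-natal factor multiplying LBW in MR |
| `pu_slope` | 0.05 | 1/y | paternity-uncertainty ramp (0 → 0.25 over 15–20) |
| `stunting_catchup_factor` | 0.75 | – | S / LBW |
| `mm_k4`, `mm_k5`, `mm_k6` | 0.485, 0.033, 2.3e-5 | –, 1/y, 1/y³ | maternal-mortality cubic |

`ibi_override` and `pu_override` replace their ramp with a fixed value;
`mortality_multiplier` and `stunting_multiplier` scale MR and S. These four
knobs express all eight built-in scenarios. The mortality shifts (±10 %/20 %)
are applied as a multiplicative factor on the full MR before clipping —
mathematically identical to scaling the post-natal factor, since MR is a
product, and the simplest reading of "shift post-natal mortality while
keeping its link to low birth weight".

## Numerical choices

- **Extrapolation.** The ramps are defined on 15–20 y but scenario optima
  reach past 20 y, so all ramps continue linearly and are then clipped:
  probabilities to [0, 1], the post-natal factor floored at 0. TF is floored
  at 0, so M ≥ 34 y yields zero fitness rather than an error. An IBI driven
  non-positive (only possible with a user-supplied negative slope) raises.
- **Optimisation.** The fitness surfaces are piecewise smooth and extremely
  flat near their maxima (the basic maternal objective varies by < 0.01
  offspring over ~0.5 y), so the optimiser is an inclusive grid search with
  ties broken toward the lowest age — deterministic and exact to the step.
  Default grid 15–25 y at 0.1 y, covering every built-in scenario's optimum
  at the reporting precision. A boundary optimum emits a warning since it
  means the range truncated the search. Derivative methods were deliberately
  avoided: after clipping the objective is piecewise polynomial with kinks.
- **Rounding.** Internal values are full-precision floats; rounding happens
  only in the reporting layer (ages and offspring to 1 dp, rates as
  percentages to 1 dp, matching the reference table's precision). CSV/JSON
  outputs keep full precision; only the pretty renderer rounds.

## Reference values and known inconsistencies

`validation.REFERENCE_TABLE` stores the published per-scenario reference
cells (optimal ages, fitness, mortality %, stunting %), and
`discrepancy_table()` recomputes every cell from the stated equations at the
printed optimum ages. Most cells reproduce exactly at 1-dp rounding (the
entire basic and contraception rows, the monitoring-with-support fitness
values). A handful do not follow from the published equations themselves —
e.g. the public-health row's mortality (printed 39.5, recomputed 38.7), the
education row's mortality (14.0 vs 15.3), the no-support monitoring row's
mortality (52.6) and stunting (28.5 vs the 42.8 implied by the tripled
stunting rule), and the maternal-mortality curve endpoints (printed
0.070/0.016 vs 0.068/0.009 from the stated constants). This package
reproduces the **equations**, not those cells; the audit table makes each gap
visible instead of silently patching it, and the test suite asserts only the
internally consistent cells.

The reference optima themselves sit on near-flat objectives: our grid search
finds the basic-model maternal optimum at 17.3 y with LRF 4.093, while the
reference prints 17.6 y with LRF within 0.01 of that — both are maxima to
well inside the model's meaningful precision. Optima are therefore validated
to ±0.5 y, while rates and fitness are validated exactly at the printed ages
via the `--at-ages` fixed-age mode, separating "reproduce the printed cells"
from "reproduce the unreported optimiser settings".

## What the tests do and do not show

The model is a stylised thought experiment: linear dose-response ramps with
round-number anchors, no heterogeneity, no feedback from outcomes to
behaviour, no empirical fitting. Passing tests show the implementation
computes this model exactly and that its qualitative conclusions (fathers'
optima earlier than mothers' under ramp PU; convergence under fixed PU) are
structural properties, not numerical accidents. They say nothing about how
well the ramps describe any real population — applying the model to data
would require re-estimating every slope and intercept.

## Limitations

- Single decision variable; no joint optimisation over, e.g., IBI and M.
- Scenario overrides are static; no time-varying or scheduled interventions.
- Remarriage, polygyny, offspring sex ratio and multi-generation household
  dynamics are out of scope.
- The grid optimiser is exact only to its step; the default 0.1 y matches the
  reporting precision but a flat objective means the argmax, unlike the
  maximum value, is not a robust quantity.
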