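# conflictsim

A deterministic evolutionary-demography simulator of **parental conflict over
women's age at marriage**. In many patrilocal agricultural societies, girls
are married early; an evolutionary question is why men's families favour this
even though it raises child mortality and undernutrition. `conflictsim`
implements a closed-form life-history model in which a woman's marriage age
*M* drives her fertility schedule and her children's survival, and computes
the marriage age that maximises each parent's **lifetime reproductive fitness
(LRF)** — the number of offspring surviving to age 5. The gap between the
maternal and paternal optima quantifies the sexual conflict.

It is intended for evolutionary demographers, global-health modellers and
students exploring how interventions (contraception, public-health programmes,
women's education, household "monitoring" of wives) shift each parent's
optimum.

## The model

All quantities are linear (or, for maternal mortality, cubic) dose-response
functions of marriage age *M* in years, anchored at a reference age of 15:

```
AFP = M + 1                                 age at first pregnancy
IBI = 2 + 0.25 (M − 15)                     inter-birth interval (years)
TF  = (35 − AFP) / IBI                      total fertility (offspring)
LBW = 0.9 − 0.1 (M − 15)                    low-birth-weight risk
MR  = LBW · (0.7 − 0.065 (M − 15))          child mortality before age 5
S   = 0.75 · LBW                            stunting prevalence
PU  = 0.05 (M − 15)                         paternity uncertainty
MMR = 0.485 − 0.033 M + 0.000023 M³         maternal mortality (optional)

maternal LRF = TF · (1 − MR) · (1 − MMR)
paternal LRF = maternal LRF · (1 − PU)
```

Probabilities are clipped to [0, 1] so the ramps extrapolate safely beyond
the illustrative 15–20 y band. Because paternity uncertainty rises with
marriage age while the other husband-side costs do not, the paternal optimum
sits *earlier* than the maternal one in every ramp-PU scenario — the model's
central result.

Eight built-in scenarios override parameters declaratively: `basic`,
`contraception` (IBI fixed at 3 y), `public_health` (child mortality ×0.9),
`economic_shock` (×1.2), `education` (IBI 3 y, mortality ×0.9, PU fixed 0.2),
`monitoring_with_support` (IBI 2 y, PU 0.01), `monitoring_without_support`
(additionally mortality ×1.2, stunting ×3), and `maternal_mortality`.
Custom scenarios load from a JSON config file.

## Worked example

```bash
$ conflictsim evaluate --scenario basic --age 17.6
 marriage_age  afp  ibi  total_fertility  lbw_risk  postnatal_factor  child_mortality_rate  stunting_rate  paternity_uncertainty  maternal_mortality_risk  maternal_lrf  paternal_lrf
         17.6 18.6  2.7              6.2      0.64             0.531                  0.34           0.48                   0.13                      0.0           4.1           3.6
```

A woman married at 17.6 y first gives birth at 18.6, bears 6.2 children at
2.65-year intervals; 34% die before age 5 and 48% of survivors are stunted,
leaving a maternal LRF of 4.1 offspring (paternal 3.6 after the 13%
paternity discount).

The full conflict table (both parents' optima per scenario, found by grid
search over 15–25 y at 0.1 y steps):

```bash
$ conflictsim table --scenarios all
                  scenario  maternal_opt_age  paternal_opt_age  delta_age  maternal_lrf  paternal_lrf  ...
                     basic              17.3              16.2       -1.1           4.1           3.7  ...
             contraception              20.1              18.2       -1.9           4.0           3.2  ...
```

A negative `delta_age` (paternal − maternal) is the conflict: in the basic
model fathers maximise fitness when wives marry about a year younger than is
optimal for the mothers themselves. Fixing paternity uncertainty (education
or monitoring scenarios) makes the conflict vanish (`delta_age = 0`).

Other entry points: `conflictsim sweep` writes outcome trajectories over an
age grid (optionally plotted), `conflictsim scenarios` lists the registry,
`conflictsim table --at-ages 17.6,16.4` evaluates at fixed ages instead of
optimising, and `conflictsim discrepancies` prints the reference-value audit
(see `docs/methods.md`). Everything is also available as a library:

```python
import conflictsim as cs
params = cs.apply_scenario(cs.ModelParameters(), cs.get_scenario("contraception"))
cs.optimize_marriage_age(params, "maternal")   # (20.1, 3.967...)
```

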