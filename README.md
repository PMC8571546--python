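# wcdcma

Decision-analytic Markov cohort model comparing a **wearable cardioverter
defibrillator (WCD)** against prolonged stay in a low-intensity hospital as
a bridge between ICD explantation (for device infection) and reimplantation,
from the perspective of the Italian National Health Service.

Patients whose infected ICD has been removed carry a high short-term risk of
sudden cardiac arrest but cannot be reimplanted until the infection clears.
The two bridging strategies are assumed equally effective, so the comparison
is a **cost-minimization analysis (CMA)**: only costs differ between arms.

## Model

A monthly-cycle state-transition cohort model with four states:

- **BRIDGE** — the one-month post-explant period (WCD at home, or in-hospital
  stay). SCA incidence `p_sca`, event survival 85.5% with certain VT/VF
  termination; survivors are reimplanted (procedural death `p_proc`).
- **POST_ICD** — alive with a reimplanted device; monthly risks of
  heart-failure hospitalization, new device infection (re-explant, returning
  the patient to BRIDGE), lead failure, and death.
- **DEAD_CARDIAC / DEAD_OTHER** — absorbing.

Mortality is split into age-increasing general-population mortality (from a
life table, `q_annual` converted to monthly probabilities on the hazard
scale) and a constant monthly **excess cardiac mortality** calibrated from
ICD-trial summaries. Costs accrue per cycle and are discounted at 3%/year,
`(1+r)^{-t/12}`. Because the arms share one cohort trace, the discounted
cost difference is exactly affine in each bridge episode cost:

    Δ = (c_WCD − c_stay) · E[bridge episodes, discounted]

where `c_WCD = €3600` and `c_stay = €250/day × 21 days = €5250`. The
expected number of bridge episodes per patient exceeds 1 whenever
reinfection is possible; the model exposes this multiplier directly.

An individual-level microsimulation (independent per-path event draws)
validates the cohort engine, and a synthetic-data module generates
Gompertz–Makeham life tables and plausible parameter bundles.

## Worked example

```python
import wcdcma as w

params = w.load_parameters(None, w.synthetic_life_table())  # all defaults
result = w.run_cma(params)
print(result.to_table().round(2))
print("episodes per patient:", round(result.bridge_episode_multiplier, 4))
print("break-even stay cost:", round(w.threshold_standard_care_cost(params), 2))
```

prints

```
                     treatment       cost  cost_discounted
0                          WCD  120016.51         94384.75
1             Standard of care  121880.43         96195.96
2  WCD versus standard of care   -1863.92         -1811.21
episodes per patient: 1.1296
break-even stay cost: 3600.0
```

The WCD arm costs €1863.92 less per patient over a lifetime (€1811.21
discounted); the expected 1.13 bridge episodes per patient reflect the
reinfection loop (each reinfection re-incurs a bridge episode and a
reimplantation). The break-even standard-care cost equals the WCD price
exactly — below a €3600 stay cost the WCD would no longer save money.

These numbers use the default configuration: main-text inputs at their
published values and documented placeholder values for the inputs published
only in supplementary material (DRG tariffs, monthly post-ICD cost, and the
monthly complication probabilities); see `docs/methods.md`. Exact values
can be supplied via a YAML config:

```sh
wcd-cma basecase --config my_params.yaml --life-table istat.csv --out results/
wcd-cma sensitivity --param standard_care_cost --range -0.3:0.3 --plot
wcd-cma threshold
wcd-cma tornado
wcd-cma validate --n-paths 100000 --seed 1
wcd-cma synth --seed 1   # emit a synthetic life table + config
```

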