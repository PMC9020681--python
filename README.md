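# nvaf-cea

Markov cohort cost-effectiveness model of oral anticoagulants for stroke
prevention in non-valvular atrial fibrillation (NVAF), from the Spanish
National Health System perspective. The package reimplements a published
real-world-evidence analysis comparing three non-vitamin-K oral
anticoagulants (NOACs) — rivaroxaban, dabigatran and apixaban — each against
a vitamin K antagonist (VKA), including its deterministic (tornado) and
probabilistic sensitivity analyses and scenario analyses. It is aimed at
health-economics and HTA researchers who want a transparent, testable,
scriptable version of this class of model.

## The model in brief

A cohort enters at age 73.4 in stable AF and moves in 3-month cycles over a
30-year horizon through acute/post states for minor and major ischaemic
stroke, myocardial infarction, intracranial haemorrhage, a GI-bleeding
tunnel state, and death, crossed with treatment status (initial drug, VKA
after a switch, off treatment). Event rates `r` per 100 patient-years
convert to cycle probabilities by `p = 1 − exp(−r t)`; treatment hazard
ratios and age-specific stroke relative risks act in the rate domain,
`p' = 1 − (1−p)^h`. Discontinuation follows four time-since-initiation
bands and each arm's discontinuation hazard ratio. Costs and QALYs accrue
at cycle start, discounted at 3%/year, and comparators are summarised as
ICER = Δcost/ΔQALY versus VKA, with a cost-effectiveness acceptability
curve (CEAC) from the net-monetary-benefit rule over 1,000 probabilistic
draws. Full details and design rationale: `docs/methods.md`.

## Worked example

```python
from nvaf_cea import load_parameters, run_cohort, compare_arms

params = load_parameters()            # packaged inputs + calibrated life table
_, vka  = run_cohort(params, "vka")
_, riva = run_cohort(params, "rivaroxaban")
inc = compare_arms(vka, riva)
print(f"VKA: €{vka.total_cost:,.0f}, {vka.qalys:.2f} QALYs")
print(f"rivaroxaban vs VKA: Δ€{inc.delta_cost:,.0f}, ΔQALY {inc.delta_qaly:.3f}, "
      f"ICER €{inc.icer_qaly:,.0f}/QALY")
```

prints

```
VKA: €20,312, 7.18 QALYs
rivaroxaban vs VKA: Δ€363, ΔQALY 0.058, ICER €6,308/QALY
```

i.e. a lifetime VKA strategy costs ~€20.3k and yields 7.18 discounted
QALYs; switching the cohort to rivaroxaban buys 0.058 extra QALYs for €363
extra — about €6.3k per QALY, well under the €22,000/QALY willingness-to-pay
reference used for Spain. The same comparison gives €7.4k/QALY for
dabigatran and €36.6k/QALY for apixaban (whose stroke hazard ratio vs VKA
is ~1, so its benefit rests on avoided bleeds alone).

The numbered scripts under `analysis/` run the full study: `00_calibrate.py`
(documented calibration of the synthetic life table and administration
costs), `01_base_case.py`, `02_tornado.py`, `03_psa.py`, `04_scenarios.py`,
`05_microsim_validation.py`; each writes its tables under `results/`. The
same steps are available as a CLI:

```bash
nvaf-cea run                          # base-case table, published layout
nvaf-cea psa --n 1000 --seed 42       # CE-plane scatter + CEAC
nvaf-cea dsa --arm rivaroxaban        # tornado CSV
nvaf-cea scenario                     # age-77 / 10y / 20y horizons
nvaf-cea synth-lifetable --out lt.csv # Gompertz life-table generator
```

All inputs live in an editable YAML (`src/nvaf_cea/data/default_parameters.yaml`;
every uncertain value carries its one-way range and PSA distribution family)
plus a two-column `age,qx` life-table CSV — pass your own with
`--config`/`--life-table` or `load_parameters(path, life_table)`.

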