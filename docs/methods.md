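# Methods

## The model

`nvaf_cea` is a Markov cohort state-transition model of first-line oral
anticoagulation for stroke prevention in non-valvular atrial fibrillation
(NVAF), built to reimplement a published Spanish NHS real-world
cost-effectiveness analysis of rivaroxaban, dabigatran and apixaban, each
versus a vitamin K antagonist (VKA).

The cohort enters at age 73.4 in stable AF on its assigned drug and is
propagated in 3-month cycles over a 30-year horizon. Health states are
stable AF; acute and post states for minor ischaemic stroke, major ischaemic
stroke, myocardial infarction (MI) and intracranial haemorrhage (ICH);
an acute gastrointestinal (GI) bleeding state with no post state (survivors
return to stable AF); and absorbing death. Acute states are one-cycle
tunnels. Health states are crossed with a treatment dimension: on the
initial drug, on VKA after a switch (with quarterly sub-states, see
*Persistence* below), or off treatment — 71 composite states in all.

Costs (drug acquisition, administration/INR monitoring, event management)
and health outcomes (utility-weighted and unweighted life-time) accrue at
cycle start and are discounted at 3% per annum, `(1+r)^(−t)` evaluated at
each cycle-start time. There is no half-cycle correction (a flag exists for
audit). Expected event counts are undiscounted acute-state occupancies
summed over the horizon.

### Event risks

Baseline VKA-arm event rates (per 100 patient-years) convert to per-cycle
probabilities by the constant-hazard form `p = 1 − exp(−r t)`; this
reproduces the published 3-month probabilities at printed precision (GI
0.260%, ICH 0.085%). A linear `r·t` mode exists for audit only. The
minor/major split of ischaemic stroke uses a minor fraction of 0.41, chosen
so the derived 3-month probabilities equal the printed 0.114% / 0.163%; the
source split itself is cited but not printed in the original tables.

Hazard ratios (and the age-specific stroke relative risks, reference band
70–74) act in the rate domain: `p' = 1 − (1 − p)^h`. This makes composition
exact (`h1` then `h2` equals `h1·h2`) and is the internally consistent
counterpart of the exponential rate conversion.

Treatment exposure determines event risk in stable AF only: the initial
drug's hazard ratios while on it, VKA baseline after a switch, and
off-treatment multipliers otherwise. Patients in post-event states face
subsequent events at the treatment-independent VKA baseline, reflecting the
predecessor model's convention that trajectories after a first event no
longer depend on the assigned drug.

**Off-treatment risk.** The source tables give no event rates for patients
who stop anticoagulation, yet most of the modelled cohort is off treatment
within a few years, so this input matters. Defaults are anchored in the
classic anticoagulation effect sizes rather than fitted: untreated stroke
risk is set to 1/0.36 ≈ 2.78 times the VKA-treated baseline (the ~64%
relative risk reduction of VKA versus no treatment), ICH and GI bleeding to
0.5 times (anticoagulation roughly doubles bleeding), MI unchanged. The
multiplier is configurable as a scalar or per-event mapping; setting it to 1
(off-treatment risk equal to treated baseline) collapses the persistence
channel and roughly quarters the incremental QALYs of all comparators.

### Mortality

Background mortality comes from an annual life table (`qx` by integer age,
converted per cycle as `1 − (1−qx)^0.25`, ages floored, lookups clamped to
the table range). Event mortality combines with it as independent risks:
acute case fatality in the acute cycle, per-cycle excess mortality in the
post-major-stroke, post-MI and post-ICH states. Events and death otherwise
compete additively within a cycle, so the baseline transition entries equal
the printed per-cycle probabilities exactly; only where background `qx`
approaches 1 at the top of the life table does the death channel absorb
just the mass events leave over.

### Persistence and switching

Discontinuation of the initial drug uses four time-since-initiation bands
(0–3, 3–6, 6–12, 12+ months) of per-cycle probabilities, scaled per arm by
its discontinuation hazard ratio. A discontinuing patient either switches
to VKA (the arm's switch proportion) or stops treatment. Switching to VKA
starts a *new* treatment episode: quarterly sub-states restart the
persistence clock through the same four bands (at the VKA hazard), and a
VKA→VKA re-switch has no consequence — in the VKA arm itself, switchers
therefore simply remain on VKA. This reading is forced by the accounting:
treating switched patients as permanently persistent on VKA would require
negative per-cycle administration costs to reconcile with the published
lifetime administration totals. Surviving a major ischaemic stroke or an
ICH permanently discontinues the initial drug (configurable); off-treatment
patients never re-initiate.

### Costs and utilities

Acute events incur a one-off acute cost plus, for the fraction of events
going to rehabilitation, a one-off rehabilitation cost (the stroke
rehabilitation cost serves minor and major stroke; the bleeding one serves
ICH and GI). Post states accrue monthly follow-up costs (the bleeding
follow-up cost applies to post-ICH only). Drug acquisition uses
365.25/4 = 91.3125 days per cycle; administration is a per-cycle cost for
any on-treatment occupancy. Utilities are state-specific weights in [0, 1]
with no treatment-related decrements; death is 0.

### Calibrated inputs (`analysis/00_calibrate.py`)

Two inputs of the original analysis are not published and are calibrated
once, openly:

* **Life table.** The original uses national Spanish mortality tables,
  which are not shipped. The packaged stand-in is a synthetic
  Gompertz–Makeham table (`qx = 1 − exp(−(a + b·e^{c·age}))`, a = 5e-4,
  c = 0.105) whose level `b` is fitted by a one-dimensional root find so the
  VKA arm reproduces the published discounted life expectancy (9.96 LY);
  the fitted `b` ≈ 1.083e-5 gives qx(73) ≈ 0.023, plausible for Spain.
* **Administration costs.** Per-cycle administration/monitoring costs are
  unprinted. Administration spending is linear in them, so each arm's value
  is solved exactly from the published lifetime administration totals
  (VKA €99.47/cycle ≈ €33/month of INR monitoring; NOACs ≈ €47–50/cycle).

## Sensitivity analyses

* **One-way (tornado).** Every input carrying a printed range is set to its
  low/high bound with all else at base; both arms re-run; entries sorted by
  ICER spread. Inputs specific to another comparator are excluded from a
  given tornado.
* **Probabilistic.** Printed ranges are read as 95% intervals
  (SD = range/3.92). Probabilities, proportions and utilities are drawn
  from method-of-moments betas (mean = base); costs from gammas; hazard
  ratios from lognormals with median at the base value — the source
  assigns betas to hazard ratios, but a [0,1] beta cannot represent the GI
  HR of 1.22, so the lognormal is the default and a beta rescaled onto
  [low, high] is available for audit. Infeasible beta moments fall back to
  the flattest beta with α, β ≥ 1, with a warning. Draws are independent
  across parameters (no correlation structure is published). The CEAC
  reports the fraction of draws with positive net monetary benefit,
  λ·ΔQALY − Δcost, per threshold. The default draw count is 1,000 (the
  original's iteration count is unstated).
* **Scenarios.** Entry age 77; 10- and 20-year horizons; and an
  alternative hazard-ratio table that must be user-supplied because the
  original's alternative effect sizes are not printed.

## Synthetic data and validation

The synthetic module generates everything the pipeline needs without
downloads: Gompertz–Makeham life tables (written in the same two-column CSV
the loader reads), random parameter sets drawn from the fitted uncertainty
distributions, and a patient-level microsimulation that samples individual
trajectories from the exact per-cycle transition distributions of the
cohort engine. The microsimulation is the engine's independent oracle:
cohort QALYs, costs and event counts must lie within three Monte-Carlo
standard errors of the patient-level means (checked at 100,000 patients in
the acceptance suite and across randomly perturbed parameter sets in the
unit tests). What the synthetic life table does *not* emulate: cohort
heterogeneity, sex-specific mortality, period effects — so agreement with
published absolute totals shows internal consistency under a plausible
mortality stand-in, not that Spanish vital statistics were reproduced.

## Numerical choices

Occupancy is propagated as a dense vector against per-cycle 71×71 matrices
built once per run (~7 ms per arm-run); mass conservation is enforced to
1e-9 each cycle and tested to 1e-10. Degenerate inputs: zero rates, zero
mortality and unit utilities reduce to closed forms (30 undiscounted QALYs
over the horizon; the 3%-discounted 30-year quarterly annuity equals
19.9666). ICERs are reported as undefined — never a division error — when
the effect difference is zero; strategies that save money and gain QALYs
are flagged dominant.

## Known limitations

* The published model's full internals (national life table, predecessor
  submission conventions, off-treatment risks) are not printed; with the
  documented calibrations this implementation reproduces the published VKA
  arm almost exactly (costs €20,312 vs €20,307; QALYs 7.18 vs 7.16) and the
  comparator rank order, but rivaroxaban's increments remain compressed
  (ΔQALY 0.06 vs 0.08; ICER ~6,300 vs 952 €/QALY), so absolute ICER
  agreement is limited for the arms whose benefit is persistence-driven.
* Treatment effects apply only in stable AF; no re-initiation after
  stopping; no dose adjustment, renal function or other covariates.
* Event counts depend strongly on the off-treatment multipliers, for which
  no source values are printed.
* Costs are consumed as printed €2018; no inflation arithmetic.
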