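"""Synthetic inputs and the patient-level validation oracle.

Three generators keep the pipeline self-contained without external data:

* parametric Gompertz-Makeham life tables standing in for national mortality
  tables (the packaged default is calibrated so the reference arm's survival
  is plausible for an elderly Spanish cohort);
* random parameter sets drawn from each input's fitted uncertainty
  distribution (the same machinery the probabilistic sensitivity analysis
  uses);
* a patient-level microsimulation that samples individual trajectories from
  the exact per-cycle transition distributions of the cohort engine, used as
  an independent oracle for the cohort results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import engine
from .parameters import LifeTable, ParameterError, ParameterSet
from .sensitivity import fit_distribution

__all__ = ["GompertzSpec", "make_life_table", "perturb_parameters",
           "microsimulate", "MicrosimResult"]


@dataclass(frozen=True)
class GompertzSpec:
    """Gompertz-Makeham annual mortality hazard ``a + b * exp(c * age)``.

    ``makeham`` is the age-independent baseline hazard, ``level`` the scale of
    the senescent component and ``shape`` its exponential age coefficient.
    """

    makeham: float = 0.0005
    level: float = 2.7e-5
    shape: float = 0.105
    age_min: int = 50
    age_max: int = 110

    def __post_init__(self):
        if self.makeham < 0 or self.level < 0 or self.shape <= 0:
            raise ParameterError(
                "Gompertz spec needs makeham >= 0, level >= 0, shape > 0")
        if self.age_min >= self.age_max:
            raise ParameterError("age_min must be below age_max")

    def annual_qx(self, age: np.ndarray) -> np.ndarray:
        hazard = self.makeham + self.level * np.exp(self.shape * np.asarray(age, float))
        return -np.expm1(-hazard)


def make_life_table(spec: GompertzSpec = GompertzSpec()) -> LifeTable:
    """Build a synthetic life table from a Gompertz-Makeham hazard.

    ``qx(age) = 1 - exp(-(a + b exp(c age)))``; values that would exceed 1
    are capped with a warning.
    """
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = spec.annual_qx(ages)
    if np.any(qx[:-1] >= 1.0):
        warnings.warn("Gompertz hazard drives qx to 1 before the terminal age; "
                      "capping at 1")
    qx = np.minimum(qx, 1.0)
    return LifeTable(ages=ages, qx=qx)


def perturb_parameters(params: ParameterSet, seed: int, scale: float = 1.0) -> ParameterSet:
    """Draw one random parameter set from the fitted uncertainty model.

    Every registry entry with a sampling family is drawn from its fitted
    distribution with the spread multiplied by ``scale``; ``scale = 0``
    returns the base values unchanged.
    """
    if scale < 0:
        raise ParameterError(f"scale must be >= 0, got {scale}")
    rng = np.random.default_rng(seed)
    overrides: dict[str, float] = {}
    for pid, spec in params.uncertain.items():
        if not spec.in_psa:
            continue
        dist = fit_distribution(spec, sd_scale=scale)
        overrides[pid] = float(dist.sample(rng))
    if scale == 0.0:
        return params
    return params.with_overrides(overrides)


@dataclass(frozen=True)
class MicrosimResult:
    """Aggregated microsimulation outcomes with Monte-Carlo standard errors."""

    arm: str
    n_patients: int
    qalys: float
    qalys_se: float
    life_years: float
    life_years_se: float
    total_cost: float
    total_cost_se: float
    events: dict[str, float]
    events_se: dict[str, float]


def microsimulate(params: ParameterSet, arm, n_patients: int,
                  seed: int) -> MicrosimResult:
    """Simulate individual patient trajectories as an engine oracle.

    Each patient's path is sampled cycle by cycle from the same transition
    distributions the cohort engine uses; discounted outcomes are accrued
    with the cohort engine's cycle-start conventions, so the aggregated means
    estimate the cohort results with Monte-Carlo error ``O(1/sqrt(n))``.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    profile = engine._resolve_arm(params, arm)
    st = params.settings
    n_cycles = st.n_cycles
    cl = st.cycle_length
    A = engine.build_transition_matrices(params, profile)
    cum = A.cumsum(axis=2)

    u = params.utilities
    util = np.zeros(engine.N_STATES)
    alive = np.zeros(engine.N_STATES)
    drug_daily = np.zeros(engine.N_STATES)
    admin = np.zeros(engine.N_STATES)
    state_cost = np.zeros(engine.N_STATES)   # acute + follow-up per cycle
    c = params.costs
    u_by_health = {
        "stable_af": u.stable_af,
        "acute_minor_is": u.minor_is, "post_minor_is": u.post_minor_is,
        "acute_major_is": u.major_is, "post_major_is": u.post_major_is,
        "acute_mi": u.mi, "post_mi": u.post_mi,
        "acute_ich": u.ich, "post_ich": u.post_ich,
        "acute_gi": u.gi,
    }
    acute_cost = {
        "acute_minor_is": c.acute_minor_is + c.rehab_prop_minor_is * c.rehab_is,
        "acute_major_is": c.acute_major_is + c.rehab_prop_major_is * c.rehab_is,
        "acute_mi": c.acute_mi,
        "acute_gi": c.acute_gi + c.rehab_prop_gi * c.rehab_bleeding,
        "acute_ich": c.acute_ich + c.rehab_prop_ich * c.rehab_bleeding,
    }
    monthly = {
        "post_minor_is": c.monthly_minor_is,
        "post_major_is": c.monthly_major_is,
        "post_mi": c.monthly_mi,
        "post_ich": c.monthly_bleeding,
    }
    vka = params.treatments["vka"]
    for h in engine.HEALTH_STATES:
        for t in engine.TX_STATES:
            i = engine.state_index(h, t)
            util[i] = u_by_health[h]
            alive[i] = 1.0
            if t == "on_initial":
                drug_daily[i] = profile.daily_drug_cost
                admin[i] = profile.admin_cost_per_cycle
            elif t.startswith("switched"):
                drug_daily[i] = vka.daily_drug_cost
                admin[i] = vka.admin_cost_per_cycle
            state_cost[i] = acute_cost.get(h, 0.0) + 12.0 * cl * monthly.get(h, 0.0)
    per_cycle_cost = drug_daily * st.days_per_cycle + admin + state_cost

    acute_states = {engine.state_index(a, t): ev
                    for ev, a in engine._EVENT_TO_ACUTE.items()
                    for t in engine.TX_STATES}
    event_names = list(engine._EVENTS)
    acute_index = np.full(engine.N_STATES, -1, dtype=int)
    for idx, ev in acute_states.items():
        acute_index[idx] = event_names.index(ev)

    rng = np.random.default_rng(seed)
    state = np.full(n_patients, engine.state_index("stable_af", "on_initial"), dtype=int)
    qaly = np.zeros(n_patients)
    ly = np.zeros(n_patients)
    cost = np.zeros(n_patients)
    ev_counts = np.zeros((n_patients, len(event_names)))

    for k in range(n_cycles):
        df = (1.0 + st.discount_rate) ** (-cl * k)
        qaly += df * cl * util[state]
        ly += df * cl * alive[state]
        cost += df * per_cycle_cost[state]
        in_acute = acute_index[state]
        hit = in_acute >= 0
        if np.any(hit):
            ev_counts[hit, in_acute[hit]] += 1.0
        r = rng.random(n_patients)
        state = (r[:, None] > cum[k][state]).sum(axis=1)

    events = {}
    events_se = {}
    for j, ev in enumerate(event_names):
        events[ev] = float(ev_counts[:, j].mean())
        events_se[ev] = float(ev_counts[:, j].std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0
    events["is"] = events["minor_is"] + events["major_is"]
    events_se["is"] = float((ev_counts[:, 0] + ev_counts[:, 1]).std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0

    sd = (lambda x: float(x.std(ddof=1) / np.sqrt(n_patients))) if n_patients > 1 else (lambda x: 0.0)
    return MicrosimResult(
        arm=profile.name,
        n_patients=n_patients,
        qalys=float(qaly.mean()), qalys_se=sd(qaly),
        life_years=float(ly.mean()), life_years_se=sd(ly),
        total_cost=float(cost.mean()), total_cost_se=sd(cost),
        events=events, events_se=events_se,
    )
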