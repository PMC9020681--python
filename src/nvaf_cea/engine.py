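"""Markov cohort engine.

The composite state space crosses ten health states (stable AF, one acute and
one post state per event type, GI bleeding without a post state) with three
treatment statuses (on the initial drug, switched to VKA, off treatment) plus
an absorbing dead state: 31 states in all.

Acute states are tunnel states occupied for exactly one cycle.  Transition
probabilities vary by cycle through three channels: cohort age (background
mortality and the age-specific stroke relative risk), and time since
initiation (the discontinuation band).  The whole horizon's transition
matrices are therefore built up front as a ``(n_cycles, 31, 31)`` array and
the cohort vector is propagated through them; outcome accrual is a set of
vectorised dot products over the resulting trace.

Conventions: state membership, costs and utilities are evaluated at cycle
start; there is no half-cycle correction (a flag exists for audit); the
discount factor for cycle ``k`` is ``(1 + rate)**(-k * cycle_length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import (
    ParameterError,
    ParameterSet,
    TreatmentProfile,
    apply_hazard_ratio,
)

__all__ = [
    "HEALTH_STATES", "TX_STATES", "STATE_NAMES", "N_STATES", "DEAD",
    "state_index", "discount_factor", "build_transition_matrices",
    "build_transition_distribution", "run_cohort", "compare_arms",
    "CohortTrace", "ArmResult", "Incremental",
]

HEALTH_STATES = (
    "stable_af",
    "acute_minor_is", "post_minor_is",
    "acute_major_is", "post_major_is",
    "acute_mi", "post_mi",
    "acute_ich", "post_ich",
    "acute_gi",
)
# Switching to VKA starts a new treatment episode, so time since the switch
# is tracked in quarterly sub-states to drive the persistence bands (0-3,
# 3-6, 6-12 months as two quarters, then 12+ months).
SWITCHED_STATES = ("switched_q1", "switched_q2", "switched_q3", "switched_q4",
                   "switched_12plus")
TX_STATES = ("on_initial",) + SWITCHED_STATES + ("off_treatment",)
N_HEALTH = len(HEALTH_STATES)
N_TX = len(TX_STATES)
DEAD = N_HEALTH * N_TX
N_STATES = DEAD + 1

STATE_NAMES = tuple(f"{h}|{t}" for h in HEALTH_STATES for t in TX_STATES) + ("dead",)

_H = {name: i for i, name in enumerate(HEALTH_STATES)}
_T = {name: i for i, name in enumerate(TX_STATES)}

# acute tunnel states and where their survivors go
_ACUTE_DEST = {
    "acute_minor_is": "post_minor_is",
    "acute_major_is": "post_major_is",
    "acute_mi": "post_mi",
    "acute_ich": "post_ich",
    "acute_gi": "stable_af",       # GI bleeding has no post state
}
_EVENT_TO_ACUTE = {
    "minor_is": "acute_minor_is",
    "major_is": "acute_major_is",
    "mi": "acute_mi",
    "gi": "acute_gi",
    "ich": "acute_ich",
}
_EVENTS = ("minor_is", "major_is", "mi", "gi", "ich")


def state_index(health: str, tx: str | None = None) -> int:
    """Index of a composite state; ``state_index("dead")`` for the dead state."""
    if health == "dead":
        return DEAD
    return _H[health] * N_TX + _T[tx]


def discount_factor(time: float, rate: float):
    """Present-value multiplier ``(1 + rate)**(-time)`` (vectorised over time)."""
    if rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {rate}")
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ParameterError("time must be >= 0")
    out = (1.0 + rate) ** (-t)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def _resolve_arm(params: ParameterSet, arm) -> TreatmentProfile:
    if isinstance(arm, TreatmentProfile):
        return arm
    try:
        return params.treatments[arm]
    except KeyError:
        raise ParameterError(
            f"unknown arm {arm!r}; valid arms: {list(params.treatments)}") from None


def _hr_power(p: float, hr: np.ndarray | float) -> np.ndarray:
    """Vectorised ``1 - (1 - p)**hr`` for scalar p in [0, 1)."""
    return -np.expm1(np.asarray(hr, dtype=float) * np.log1p(-p))


def build_transition_matrices(params: ParameterSet, arm) -> np.ndarray:
    """Per-cycle transition matrices for one arm, shape ``(n_cycles, 31, 31)``.

    Construction per cycle: event probabilities by current treatment exposure
    (initial drug with its hazard ratios, VKA baseline after a switch or in
    any post-event state, VKA baseline times a configurable multiplier off
    treatment), stroke probabilities age-adjusted; death combines background
    mortality with acute case fatality or post-state excess mortality as
    independent risks; health and treatment transitions compose
    independently, except that surviving a major stroke or an intracranial
    haemorrhage forces permanent discontinuation of the initial drug.
    """
    profile = _resolve_arm(params, arm)
    st = params.settings
    n = st.n_cycles
    cl = st.cycle_length
    cp = params.cycle_probabilities
    mort = params.mortality
    disc = params.discontinuation

    k = np.arange(n)
    ages = params.cohort.entry_age + cl * k
    rr_age = np.array([params.age_risk.relative_risk(a) for a in ages])
    q_bg = np.array([mort.life_table.cycle_qx(a, cl) for a in ages])

    months = 12.0 * cl * k
    band_p = np.array([disc.probability(m) for m in months])
    p_disc = -np.expm1(profile.hr_discontinuation * np.log1p(-band_p))

    # event probabilities per cycle for the three exposures
    base = cp.as_dict()
    arm_hr = {"minor_is": profile.hr_is, "major_is": profile.hr_is,
              "mi": profile.hr_mi, "gi": profile.hr_gi, "ich": profile.hr_ich}
    mult = st.off_treatment_risk_multiplier
    p_event = {}  # (event, exposure) -> length-n vector
    for ev in _EVENTS:
        stroke = ev in ("minor_is", "major_is")
        rr = rr_age if stroke else np.ones(n)
        p_event[ev, "arm"] = _hr_power(base[ev], rr * arm_hr[ev])
        p_event[ev, "vka"] = _hr_power(base[ev], rr)
        p_event[ev, "off"] = _hr_power(base[ev], rr * mult[ev])
    exposure_by_tx = ("arm",) + ("vka",) * len(SWITCHED_STATES) + ("off",)

    # treatment-status transition probabilities (rows: from status)
    sw = profile.switch_proportion
    OFF = N_TX - 1
    ptx = np.zeros((n, N_TX, N_TX))
    if profile.vka_class:
        # a VKA->VKA switch has no consequence: switchers stay "on_initial"
        ptx[:, 0, 0] = 1.0 - p_disc * (1.0 - sw)
        ptx[:, 0, OFF] = p_disc * (1.0 - sw)
    else:
        ptx[:, 0, 0] = 1.0 - p_disc
        ptx[:, 0, 1] = p_disc * sw       # switch starts a new VKA episode
        ptx[:, 0, OFF] = p_disc * (1.0 - sw)
    # after a switch the persistence clock restarts: quarterly sub-states map
    # onto the discontinuation bands (q1 -> 0-3m, q2 -> 3-6m, q3/q4 -> 6-12m,
    # then 12+); a VKA->VKA re-switch has no consequence, so only the
    # non-re-switching share of discontinuers actually stops
    vka_prof = params.treatments["vka"]
    band_by_substate = (0, 1, 2, 2, 3)
    for j, band in enumerate(band_by_substate):
        row = 1 + j
        nxt = min(row + 1, 1 + len(band_by_substate) - 1)
        p_stop = disc.probs[band] * (1.0 - vka_prof.switch_proportion)
        ptx[:, row, OFF] = p_stop
        ptx[:, row, nxt] += 1.0 - p_stop
    ptx[:, OFF, OFF] = 1.0

    excess = {
        "stable_af": 0.0,
        "post_minor_is": 0.0,
        "post_major_is": mort.excess_post_major_is,
        "post_mi": mort.excess_post_mi,
        "post_ich": mort.excess_post_ich,
    }
    case_fatality = {
        "acute_minor_is": mort.cf_minor_is,
        "acute_major_is": mort.cf_major_is,
        "acute_mi": mort.cf_mi,
        "acute_ich": mort.cf_ich,
        "acute_gi": mort.cf_gi,
    }
    forced_off = {_EVENT_TO_ACUTE[ev] for ev in st.discontinue_after_events}

    A = np.zeros((n, N_STATES, N_STATES))
    A[:, DEAD, DEAD] = 1.0

    for h in HEALTH_STATES:
        if h in _ACUTE_DEST:  # tunnel state: resolve to destination or die
            q_d = 1.0 - (1.0 - q_bg) * (1.0 - case_fatality[h])
            surv = 1.0 - q_d
            dest = _ACUTE_DEST[h]
            for s, tx in enumerate(TX_STATES):
                i = state_index(h, tx)
                A[:, i, DEAD] += q_d
                if h in forced_off:
                    A[:, i, state_index(dest, "off_treatment")] += surv
                else:
                    for s2 in range(N_TX):
                        A[:, i, state_index(dest, TX_STATES[s2])] += surv * ptx[:, s, s2]
            continue

        # stable AF and post-event states
        q_d = 1.0 - (1.0 - q_bg) * (1.0 - excess[h])
        for s, tx in enumerate(TX_STATES):
            i = state_index(h, tx)
            if h == "stable_af":
                probs = {ev: p_event[ev, exposure_by_tx[s]] for ev in _EVENTS}
            else:
                # subsequent events are treatment-independent (VKA baseline)
                probs = {ev: p_event[ev, "vka"] for ev in _EVENTS}
            total_ev = sum(probs.values())
            if np.any(total_ev > 1.0 + 1e-12):
                raise ParameterError(
                    f"event probabilities from state {h!r} sum above 1; "
                    "inputs are inconsistent")
            # where background mortality approaches 1 (top of the life table)
            # the death channel absorbs only the mass events leave over
            q_d_eff = np.minimum(q_d, 1.0 - total_ev)
            stay = np.clip(1.0 - total_ev - q_d_eff, 0.0, 1.0)
            A[:, i, DEAD] += q_d_eff
            for ev, p in probs.items():
                dest = _EVENT_TO_ACUTE[ev]
                for s2 in range(N_TX):
                    A[:, i, state_index(dest, TX_STATES[s2])] += p * ptx[:, s, s2]
            for s2 in range(N_TX):
                A[:, i, state_index(h, TX_STATES[s2])] += stay * ptx[:, s, s2]

    return A


def build_transition_distribution(state: str, cycle_index: int,
                                  params: ParameterSet, arm) -> dict[str, float]:
    """Transition distribution out of one composite state at one cycle.

    ``state`` is a ``"health|treatment_status"`` name (or ``"dead"``) as in
    :data:`STATE_NAMES`.  Returned as a dict over destination state names with
    zero entries dropped; probabilities sum to 1.
    """
    if cycle_index < 0:
        raise ParameterError("cycle_index must be >= 0")
    try:
        i = STATE_NAMES.index(state)
    except ValueError:
        raise ParameterError(f"unknown state {state!r}") from None
    A = build_transition_matrices(params, arm)
    if cycle_index >= A.shape[0]:
        raise ParameterError(
            f"cycle_index {cycle_index} beyond horizon ({A.shape[0]} cycles)")
    row = A[cycle_index, i]
    return {STATE_NAMES[j]: float(row[j]) for j in np.nonzero(row)[0]}


# ---------------------------------------------------------------------------
# cohort simulation and outcome accrual
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortTrace:
    """State occupancy at the start of each cycle (rows ``0 .. n_cycles``)."""

    occupancy: np.ndarray        # (n_cycles + 1, N_STATES)
    ages: np.ndarray             # cohort age at each cycle start
    arm: str

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per cycle per state."""
        n = self.occupancy.shape[0]
        return pd.DataFrame({
            "cycle": np.repeat(np.arange(n), N_STATES),
            "age": np.repeat(self.ages, N_STATES),
            "state": np.tile(STATE_NAMES, n),
            "occupancy": self.occupancy.ravel(),
        })


@dataclass(frozen=True)
class ArmResult:
    """Discounted lifetime totals and expected event counts for one arm."""

    arm: str
    drug_cost: float
    admin_cost: float
    event_cost: float
    total_cost: float
    qalys: float
    life_years: float
    events: Mapping[str, float] = field(default_factory=dict)

    def to_series(self) -> pd.Series:
        data = {
            "drug_cost": self.drug_cost,
            "admin_cost": self.admin_cost,
            "event_cost": self.event_cost,
            "total_cost": self.total_cost,
            "qalys": self.qalys,
            "life_years": self.life_years,
        }
        data.update({f"events_{k}": v for k, v in self.events.items()})
        return pd.Series(data, name=self.arm)


def run_cohort(params: ParameterSet, arm) -> tuple[CohortTrace, ArmResult]:
    """Propagate the cohort over the horizon and accrue discounted outcomes.

    The cohort starts fully in (stable AF, on initial treatment).  Per cycle,
    occupancy at cycle start accrues: utility-weighted and unweighted
    life-time; drug acquisition cost (daily cost x 365.25/4 days) and
    administration cost for on-treatment occupancy (initial drug, or VKA
    after a switch); acute event management and rehabilitation costs for
    acute-state occupancy; monthly follow-up costs for post-state occupancy.
    Expected event counts are undiscounted acute-state occupancies summed
    over the horizon.
    """
    profile = _resolve_arm(params, arm)
    st = params.settings
    n = st.n_cycles
    cl = st.cycle_length
    A = build_transition_matrices(params, profile)

    occ = np.zeros((n + 1, N_STATES))
    occ[0, state_index("stable_af", "on_initial")] = 1.0
    for k in range(n):
        occ[k + 1] = occ[k] @ A[k]
        s = occ[k + 1].sum()
        if abs(s - 1.0) > 1e-9:
            raise ParameterError(f"occupancy lost mass at cycle {k}: sum={s}")

    k = np.arange(n)
    df = discount_factor(cl * k, st.discount_rate)
    if st.half_cycle_correction:
        # audit mode: average of start- and end-of-cycle membership
        occ_acc = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_acc = occ[:-1]

    # per-health-state utility replicated across treatment statuses
    u = params.utilities
    u_by_health = {
        "stable_af": u.stable_af,
        "acute_minor_is": u.minor_is, "post_minor_is": u.post_minor_is,
        "acute_major_is": u.major_is, "post_major_is": u.post_major_is,
        "acute_mi": u.mi, "post_mi": u.post_mi,
        "acute_ich": u.ich, "post_ich": u.post_ich,
        "acute_gi": u.gi,
    }
    util_vec = np.zeros(N_STATES)
    alive_vec = np.zeros(N_STATES)
    for h in HEALTH_STATES:
        for t in TX_STATES:
            i = state_index(h, t)
            util_vec[i] = u_by_health[h]
            alive_vec[i] = 1.0

    qalys = cl * float(df @ (occ_acc @ util_vec))
    life_years = cl * float(df @ (occ_acc @ alive_vec))

    on_initial = occ_acc[:, [state_index(h, "on_initial") for h in HEALTH_STATES]].sum(axis=1)
    switched = occ_acc[:, [state_index(h, t) for h in HEALTH_STATES
                           for t in SWITCHED_STATES]].sum(axis=1)
    vka_profile = params.treatments["vka"]
    drug_cost = float(df @ (on_initial * profile.daily_drug_cost
                            + switched * vka_profile.daily_drug_cost)) * st.days_per_cycle
    admin_cost = float(df @ (on_initial * profile.admin_cost_per_cycle
                             + switched * vka_profile.admin_cost_per_cycle))

    c = params.costs
    acute_cost = {
        "minor_is": c.acute_minor_is + c.rehab_prop_minor_is * c.rehab_is,
        "major_is": c.acute_major_is + c.rehab_prop_major_is * c.rehab_is,
        "mi": c.acute_mi,
        "gi": c.acute_gi + c.rehab_prop_gi * c.rehab_bleeding,
        "ich": c.acute_ich + c.rehab_prop_ich * c.rehab_bleeding,
    }
    monthly = {
        "post_minor_is": c.monthly_minor_is,
        "post_major_is": c.monthly_major_is,
        "post_mi": c.monthly_mi,
        "post_ich": c.monthly_bleeding,
    }
    months_per_cycle = 12.0 * cl
    event_cost = 0.0
    events: dict[str, float] = {}
    for ev in _EVENTS:
        acute = occ_acc[:, [state_index(_EVENT_TO_ACUTE[ev], t) for t in TX_STATES]].sum(axis=1)
        event_cost += float(df @ acute) * acute_cost[ev]
        # counts come off the uncorrected trace so they are true expected inflows
        raw = occ[:-1][:, [state_index(_EVENT_TO_ACUTE[ev], t) for t in TX_STATES]].sum(axis=1)
        events[ev] = float(raw.sum())
    for h, m_cost in monthly.items():
        post = occ_acc[:, [state_index(h, t) for t in TX_STATES]].sum(axis=1)
        event_cost += float(df @ post) * months_per_cycle * m_cost

    events["is"] = events["minor_is"] + events["major_is"]
    result = ArmResult(
        arm=profile.name,
        drug_cost=drug_cost,
        admin_cost=admin_cost,
        event_cost=event_cost,
        total_cost=drug_cost + admin_cost + event_cost,
        qalys=qalys,
        life_years=life_years,
        events=events,
    )
    trace = CohortTrace(occupancy=occ,
                        ages=params.cohort.entry_age + cl * np.arange(n + 1),
                        arm=profile.name)
    return trace, result


# ---------------------------------------------------------------------------
# incremental comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Incremental:
    """Incremental outcomes of a comparator versus a reference arm."""

    reference: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_qaly: float | None
    icer_lyg: float | None
    dominance: str | None    # "dominant", "dominated" or None

    def net_monetary_benefit(self, wtp: float) -> float:
        return wtp * self.delta_qaly - self.delta_cost


def _safe_ratio(dc: float, de: float) -> float | None:
    return dc / de if de != 0.0 else None


def compare_arms(reference: ArmResult, comparator: ArmResult) -> Incremental:
    """Incremental cost-effectiveness of ``comparator`` versus ``reference``.

    The ICER is reported when the effect difference is non-zero; a strategy
    that saves money and gains QALYs is flagged ``dominant``, one that costs
    more and loses QALYs ``dominated``.
    """
    dc = comparator.total_cost - reference.total_cost
    dq = comparator.qalys - reference.qalys
    dl = comparator.life_years - reference.life_years
    dominance = None
    if dc < 0 and dq > 0:
        dominance = "dominant"
    elif dc > 0 and dq < 0:
        dominance = "dominated"
    return Incremental(
        reference=reference.arm,
        comparator=comparator.arm,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=dl,
        icer_qaly=_safe_ratio(dc, dq),
        icer_lyg=_safe_ratio(dc, dl),
        dominance=dominance,
    )


def run_base_case(params: ParameterSet) -> dict[str, ArmResult]:
    """Run every configured arm once; keyed by arm name."""
    return {name: run_cohort(params, name)[1] for name in params.arm_names}
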