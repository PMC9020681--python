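"""Input data model for the anticoagulation cost-effectiveness model.

Everything the Markov engine consumes is assembled here: baseline clinical
event rates for the VKA arm and their per-cycle probabilities, treatment
profiles (hazard ratios versus VKA, drug and administration costs, switch
proportions), the time-varying discontinuation schedule, acute and post-event
mortality, background mortality from a life table, utilities, costs, and the
age-specific stroke risk adjustment.

Every uncertain quantity carries its one-way sensitivity range and the
distribution family used in probabilistic sensitivity analysis; those are
collected in a flat registry (``ParameterSet.uncertain``) addressed by dotted
paths such as ``"treatments.rivaroxaban.hr.is"`` so that the sensitivity
module can rebuild a perturbed ``ParameterSet`` from value overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParameterError",
    "ClinicalRates",
    "CycleProbabilities",
    "TreatmentProfile",
    "DiscontinuationSchedule",
    "MortalityInputs",
    "LifeTable",
    "UtilitySet",
    "CostSet",
    "AgeRiskTable",
    "CohortSpec",
    "ModelSettings",
    "UncertainParam",
    "ParameterSet",
    "rate_to_cycle_probability",
    "cycle_probability_to_rate",
    "apply_hazard_ratio",
    "age_relative_risk",
    "discontinuation_probability",
    "read_life_table",
    "load_parameters",
    "default_config_path",
    "default_life_table_path",
]


class ParameterError(ValueError):
    """Raised when a model input is missing, malformed or out of range."""


#: Default hazard multipliers vs the VKA-treated baseline for patients off
#: anticoagulation: untreated stroke risk ~1/0.36 of treated (a two-thirds
#: relative risk reduction on VKA); intracranial and gastrointestinal
#: bleeding roughly double on anticoagulation, so halve off it; MI unchanged.
OFF_TREATMENT_RISK_DEFAULT: dict[str, float] = {
    "minor_is": 2.78, "major_is": 2.78, "mi": 1.0, "gi": 0.5, "ich": 0.5,
}


# ---------------------------------------------------------------------------
# rate / probability conversions
# ---------------------------------------------------------------------------

def rate_to_cycle_probability(rate: float, cycle_length: float,
                              form: str = "exponential") -> float:
    """Convert an event rate per 100 person-years to a per-cycle probability.

    Parameters
    ----------
    rate
        Events per 100 person-years (non-negative).
    cycle_length
        Cycle length in years (positive).
    form
        ``"exponential"`` uses ``1 - exp(-r t)`` (constant hazard within the
        cycle); ``"linear"`` uses ``r t`` and exists for audit only.
    """
    if rate < 0:
        raise ParameterError(f"event rate must be >= 0, got {rate}")
    if cycle_length <= 0:
        raise ParameterError(f"cycle length must be > 0, got {cycle_length}")
    rt = (rate / 100.0) * cycle_length
    if form == "exponential":
        return 1.0 - math.exp(-rt)
    if form == "linear":
        return min(rt, 1.0)
    raise ParameterError(f"unknown conversion form {form!r}")


def cycle_probability_to_rate(p: float, cycle_length: float) -> float:
    """Inverse of :func:`rate_to_cycle_probability` (exponential form)."""
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"cycle probability must be in [0, 1), got {p}")
    if cycle_length <= 0:
        raise ParameterError(f"cycle length must be > 0, got {cycle_length}")
    return -math.log1p(-p) / cycle_length * 100.0


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale a per-cycle probability by a hazard ratio in the rate domain.

    Equivalent to converting ``p`` to a rate, multiplying the rate by ``hr``
    and converting back: ``1 - (1 - p)**hr``.  ``hr == 1`` is the identity and
    composition is exact: applying ``h1`` then ``h2`` equals applying
    ``h1 * h2``.
    """
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"probability must be in [0, 1), got {p}")
    if hr <= 0:
        raise ParameterError(f"hazard ratio must be > 0, got {hr}")
    return -math.expm1(hr * math.log1p(-p))


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual background death probabilities ``qx`` indexed by integer age.

    Ages must be contiguous and ascending.  Lookups clamp to the table's age
    range, so a cohort older than the terminal age keeps the terminal ``qx``.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size == 0 or ages.shape != qx.shape:
            raise ParameterError("life table needs matching 1-d age and qx columns")
        if not np.all(np.diff(ages) == 1):
            raise ParameterError("life table ages must be contiguous and ascending")
        if np.any((qx < 0) | (qx > 1)):
            bad = qx[(qx < 0) | (qx > 1)][0]
            raise ParameterError(f"life table qx outside [0, 1]: {bad}")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_qx(self, age: float) -> float:
        """Annual death probability at ``floor(age)``, clamped to the table."""
        i = int(np.clip(math.floor(age), self.min_age, self.max_age)) - self.min_age
        return float(self.qx[i])

    def cycle_qx(self, age: float, cycle_length: float) -> float:
        """Per-cycle death probability, ``1 - (1 - qx)**cycle_length``."""
        q = self.annual_qx(age)
        if q >= 1.0:
            return 1.0
        return -math.expm1(cycle_length * math.log1p(-q))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_life_table(path) -> LifeTable:
    """Read a two-column (age, qx) CSV life table; the header row is optional."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.shape[1] < 2:
        raise ParameterError(f"life table {path} must have two columns (age, qx)")
    first = df.iloc[0, 0]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    try:
        ages = df.iloc[:, 0].astype(float).to_numpy()
        qx = df.iloc[:, 1].astype(float).to_numpy()
    except ValueError as exc:
        raise ParameterError(f"life table {path} has non-numeric entries: {exc}") from None
    if np.any(ages != np.floor(ages)):
        raise ParameterError("life table ages must be integers")
    return LifeTable(ages=ages.astype(int), qx=qx)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _check_unit(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def _check_nonneg(name: str, value: float) -> float:
    if value < 0:
        raise ParameterError(f"{name} must be >= 0, got {value}")
    return float(value)


@dataclass(frozen=True)
class ClinicalRates:
    """VKA-arm baseline event rates, events per 100 person-years."""

    is_rate: float
    gi_rate: float
    ich_rate: float
    mi_rate: float
    minor_is_fraction: float  # share of ischaemic strokes that are minor

    def __post_init__(self):
        for name in ("is_rate", "gi_rate", "ich_rate", "mi_rate"):
            _check_nonneg(f"clinical_rates.{name}", getattr(self, name))
        _check_unit("clinical_rates.minor_is_fraction", self.minor_is_fraction)


@dataclass(frozen=True)
class CycleProbabilities:
    """VKA-arm per-cycle (3-month) event probabilities."""

    minor_is: float
    major_is: float
    mi: float
    gi: float
    ich: float

    def __post_init__(self):
        total = 0.0
        for name in ("minor_is", "major_is", "mi", "gi", "ich"):
            total += _check_unit(f"cycle_probabilities.{name}", getattr(self, name))
        if total > 1.0:
            raise ParameterError(
                f"per-cycle event probabilities sum to {total} > 1")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("minor_is", "major_is", "mi", "gi", "ich")}


@dataclass(frozen=True)
class TreatmentProfile:
    """One treatment arm: costs, hazard ratios versus VKA, switching."""

    name: str
    daily_drug_cost: float
    hr_is: float
    hr_mi: float
    hr_gi: float
    hr_ich: float
    hr_discontinuation: float
    switch_proportion: float
    admin_cost_per_cycle: float
    #: VKA-class arms treat a switch as VKA->VKA (no consequence); NOAC arms
    #: switch into a fresh VKA treatment episode.
    vka_class: bool = False

    def __post_init__(self):
        _check_nonneg(f"treatments.{self.name}.daily_drug_cost", self.daily_drug_cost)
        _check_nonneg(f"treatments.{self.name}.admin_cost_per_cycle",
                      self.admin_cost_per_cycle)
        _check_unit(f"treatments.{self.name}.switch_proportion", self.switch_proportion)
        for hr_name in ("hr_is", "hr_mi", "hr_gi", "hr_ich", "hr_discontinuation"):
            hr = getattr(self, hr_name)
            if hr <= 0:
                raise ParameterError(
                    f"treatments.{self.name}.{hr_name} must be > 0, got {hr}")


@dataclass(frozen=True)
class DiscontinuationSchedule:
    """Per-cycle discontinuation probabilities by time since initiation.

    Four bands: 0-3, 3-6, 6-12 and 12+ months.
    """

    probs: tuple[float, float, float, float]
    band_starts_months: tuple[float, float, float, float] = (0.0, 3.0, 6.0, 12.0)

    def __post_init__(self):
        if len(self.probs) != 4 or len(self.band_starts_months) != 4:
            raise ParameterError("discontinuation schedule needs exactly four bands")
        for i, p in enumerate(self.probs):
            _check_unit(f"discontinuation band {i}", p)
        if not all(a < b for a, b in zip(self.band_starts_months,
                                         self.band_starts_months[1:])):
            raise ParameterError("discontinuation band boundaries must increase")

    def band_index(self, months: float) -> int:
        if months < 0:
            raise ParameterError(f"months since initiation must be >= 0, got {months}")
        idx = 0
        for i, start in enumerate(self.band_starts_months):
            if months >= start:
                idx = i
        return idx

    def probability(self, months: float) -> float:
        return self.probs[self.band_index(months)]


def discontinuation_probability(months: float, schedule: DiscontinuationSchedule,
                                hr: float) -> float:
    """Band probability for ``months`` since initiation with a hazard ratio applied."""
    return apply_hazard_ratio(schedule.probability(months), hr)


@dataclass(frozen=True)
class MortalityInputs:
    """Event-related mortality plus the background life table.

    ``cf_*`` are acute case-fatality probabilities applied during the single
    acute cycle of each event; ``excess_*`` are per-cycle excess death
    probabilities applied in the corresponding post-event state.  Both combine
    with background mortality as independent risks.
    """

    cf_minor_is: float
    cf_major_is: float
    cf_mi: float
    cf_ich: float
    cf_gi: float
    excess_post_major_is: float
    excess_post_mi: float
    excess_post_ich: float
    life_table: LifeTable

    def __post_init__(self):
        for name in ("cf_minor_is", "cf_major_is", "cf_mi", "cf_ich", "cf_gi",
                     "excess_post_major_is", "excess_post_mi", "excess_post_ich"):
            _check_unit(f"mortality.{name}", getattr(self, name))


@dataclass(frozen=True)
class UtilitySet:
    """Per-state utility weights; the dead state is fixed at 0."""

    stable_af: float
    minor_is: float
    major_is: float
    post_minor_is: float
    post_major_is: float
    mi: float
    post_mi: float
    ich: float
    post_ich: float
    gi: float

    def __post_init__(self):
        for name in ("stable_af", "minor_is", "major_is", "post_minor_is",
                     "post_major_is", "mi", "post_mi", "ich", "post_ich", "gi"):
            _check_unit(f"utilities.{name}", getattr(self, name))


@dataclass(frozen=True)
class CostSet:
    """Event management costs in euros.

    Acute costs are one-off per event; monthly follow-up costs accrue in the
    post-event states; rehabilitation is a one-off applied to the fraction of
    acute events that go to rehabilitation.
    """

    acute_minor_is: float
    acute_major_is: float
    acute_mi: float
    acute_gi: float
    acute_ich: float
    monthly_minor_is: float
    monthly_major_is: float
    monthly_mi: float
    monthly_bleeding: float
    rehab_is: float
    rehab_bleeding: float
    rehab_prop_minor_is: float
    rehab_prop_major_is: float
    rehab_prop_gi: float
    rehab_prop_ich: float

    def __post_init__(self):
        for name in ("acute_minor_is", "acute_major_is", "acute_mi", "acute_gi",
                     "acute_ich", "monthly_minor_is", "monthly_major_is",
                     "monthly_mi", "monthly_bleeding", "rehab_is", "rehab_bleeding"):
            _check_nonneg(f"costs.{name}", getattr(self, name))
        for name in ("rehab_prop_minor_is", "rehab_prop_major_is",
                     "rehab_prop_gi", "rehab_prop_ich"):
            _check_unit(f"costs.{name}", getattr(self, name))


@dataclass(frozen=True)
class AgeRiskTable:
    """Age-band relative risks for ischaemic stroke (reference band RR = 1)."""

    band_starts: tuple[int, ...]
    relative_risks: tuple[float, ...]

    def __post_init__(self):
        if len(self.band_starts) != len(self.relative_risks) or not self.band_starts:
            raise ParameterError("age risk table needs matching band starts and RRs")
        if not all(a < b for a, b in zip(self.band_starts, self.band_starts[1:])):
            raise ParameterError("age risk band starts must be strictly increasing")
        if not all(r > 0 for r in self.relative_risks):
            raise ParameterError("age risk relative risks must be > 0")
        if not all(a < b for a, b in zip(self.relative_risks, self.relative_risks[1:])):
            raise ParameterError("age risk relative risks must be strictly increasing")

    def relative_risk(self, age: float) -> float:
        if age < 0:
            raise ParameterError(f"age must be >= 0, got {age}")
        a = math.floor(age)
        idx = 0
        for i, start in enumerate(self.band_starts):
            if a >= start:
                idx = i
        return float(self.relative_risks[idx])


def age_relative_risk(age: float, table: AgeRiskTable) -> float:
    """Stroke relative risk for the band containing ``floor(age)`` (clamped)."""
    return table.relative_risk(age)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort entry characteristics.

    Sex and CHA2DS2-VASc composition are reporting metadata: the engine has no
    stratified risks to apply them to.
    """

    entry_age: float
    male_fraction: float = 0.5
    cha2ds2vasc_high_fraction: float = 1.0

    def __post_init__(self):
        if self.entry_age <= 0:
            raise ParameterError(f"cohort.entry_age must be > 0, got {self.entry_age}")
        _check_unit("cohort.male_fraction", self.male_fraction)
        _check_unit("cohort.cha2ds2vasc_high_fraction", self.cha2ds2vasc_high_fraction)


@dataclass(frozen=True)
class ModelSettings:
    """Global simulation settings."""

    cycle_length: float = 0.25          # years
    horizon: float = 30.0               # years
    discount_rate: float = 0.03         # per annum, costs and effects
    wtp_threshold: float = 22000.0      # euros per QALY
    half_cycle_correction: bool = False
    rate_conversion: str = "exponential"
    #: Hazard multipliers versus the VKA-treated baseline applied to patients
    #: off anticoagulation.  A scalar applies to every event; a mapping sets
    #: them per event.  Defaults reflect the classic anticoagulation effect
    #: sizes: stroke risk roughly trebles without treatment (a two-thirds
    #: relative risk reduction on VKA), bleeding roughly halves.
    off_treatment_risk_multiplier: Mapping[str, float] | float = None
    discontinue_after_events: tuple[str, ...] = ("major_is", "ich")
    days_per_cycle: float = 365.25 / 4.0

    def __post_init__(self):
        if not 0 < self.cycle_length <= self.horizon:
            raise ParameterError(
                f"need 0 < cycle_length <= horizon, got {self.cycle_length}, {self.horizon}")
        if self.discount_rate < 0:
            raise ParameterError(f"discount rate must be >= 0, got {self.discount_rate}")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"horizon {self.horizon} is not a multiple of cycle length {self.cycle_length}")
        events = ("minor_is", "major_is", "mi", "gi", "ich")
        mult = self.off_treatment_risk_multiplier
        if mult is None:
            mult = dict(OFF_TREATMENT_RISK_DEFAULT)
        elif isinstance(mult, (int, float)):
            mult = {ev: float(mult) for ev in events}
        else:
            unknown = set(mult) - set(events)
            if unknown:
                raise ParameterError(
                    f"unknown events in off_treatment_risk_multiplier: {sorted(unknown)}")
            full = dict(OFF_TREATMENT_RISK_DEFAULT)
            full.update({k: float(v) for k, v in mult.items()})
            mult = full
        if any(v <= 0 for v in mult.values()):
            raise ParameterError("off-treatment risk multipliers must be > 0")
        object.__setattr__(self, "off_treatment_risk_multiplier", mult)
        bad = set(self.discontinue_after_events) - {"minor_is", "major_is", "mi", "gi", "ich"}
        if bad:
            raise ParameterError(f"unknown events in discontinue_after_events: {sorted(bad)}")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


@dataclass(frozen=True)
class UncertainParam:
    """One entry of the uncertainty registry.

    ``low``/``high`` are the one-way sensitivity bounds; ``dist`` is the PSA
    family tag (``beta``, ``gamma``, ``lognormal``) or ``None`` for values
    varied deterministically only.
    """

    id: str
    base: float
    low: float
    high: float
    dist: str | None
    explicit_range: bool = False

    @property
    def in_dsa(self) -> bool:
        return self.explicit_range

    @property
    def in_psa(self) -> bool:
        return self.dist is not None and self.explicit_range


@dataclass(frozen=True)
class ParameterSet:
    """The complete, validated model input bundle."""

    clinical_rates: ClinicalRates
    cycle_probabilities: CycleProbabilities
    treatments: Mapping[str, TreatmentProfile]
    discontinuation: DiscontinuationSchedule
    mortality: MortalityInputs
    utilities: UtilitySet
    costs: CostSet
    age_risk: AgeRiskTable
    cohort: CohortSpec
    settings: ModelSettings
    uncertain: Mapping[str, UncertainParam] = field(default_factory=dict)
    _config: dict = field(default_factory=dict, repr=False)
    _overrides: Mapping[str, float] = field(default_factory=dict, repr=False)

    @property
    def arm_names(self) -> tuple[str, ...]:
        return tuple(self.treatments)

    @property
    def comparator_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.treatments if n != "vka")

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """Rebuild the set with some registry values replaced (DSA/PSA plumbing)."""
        merged = dict(self._overrides)
        merged.update(overrides)
        return build_parameter_set(self._config, self.mortality.life_table,
                                   overrides=merged)

    def with_settings(self, **changes) -> "ParameterSet":
        """Rebuild with modified global settings (horizon, entry age live in config)."""
        cfg = _deep_copy(self._config)
        for key, value in changes.items():
            if key == "entry_age":
                cfg["cohort"]["entry_age"] = value
            else:
                cfg.setdefault("model", {})[key] = value
        return build_parameter_set(cfg, self.mortality.life_table,
                                   overrides=dict(self._overrides))

    def with_hazard_ratios(self, hr_table: Mapping[str, Mapping[str, float]]) -> "ParameterSet":
        """Rebuild with replacement hazard-ratio tables, ``{arm: {event: hr}}``."""
        cfg = _deep_copy(self._config)
        for arm, hrs in hr_table.items():
            if arm not in cfg["treatments"]:
                raise ParameterError(f"unknown arm in hazard-ratio table: {arm!r}")
            for event, hr in hrs.items():
                node = cfg["treatments"][arm].setdefault("hr", {})
                node[event] = {"value": float(hr)}
        return build_parameter_set(cfg, self.mortality.life_table,
                                   overrides=dict(self._overrides))


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

def _deep_copy(obj):
    if isinstance(obj, dict):
        return {k: _deep_copy(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_deep_copy(v) for v in obj]
    return obj


def _dig(cfg: Mapping, path: str):
    node = cfg
    for part in path.split("."):
        if not isinstance(node, Mapping) or part not in node:
            raise ParameterError(f"missing configuration key: {path!r}")
        node = node[part]
    return node


class _Builder:
    """Walks the raw config, applying overrides and collecting the registry."""

    def __init__(self, cfg: Mapping, overrides: Mapping[str, float]):
        self.cfg = cfg
        self.overrides = dict(overrides)
        self.registry: dict[str, UncertainParam] = {}
        self.unused = set(self.overrides)

    def value(self, path: str, *, derived_base: float | None = None,
              default: float | None = None) -> float:
        """Resolve one scalar parameter and register its uncertainty spec.

        ``derived_base`` supplies the base value for parameters whose config
        node states only ranges (per-cycle probabilities derived from rates).
        """
        try:
            node = _dig(self.cfg, path)
        except ParameterError:
            if default is None and derived_base is None:
                raise
            node = {}
        if isinstance(node, Mapping):
            base = node.get("value", derived_base if derived_base is not None else default)
            if base is None:
                raise ParameterError(f"missing value for configuration key {path!r}")
            dsa = node.get("dsa")
            explicit = dsa is not None
            if dsa is not None:
                if (not isinstance(dsa, (list, tuple)) or len(dsa) != 2
                        or dsa[0] > dsa[1]):
                    raise ParameterError(f"malformed dsa range for {path!r}: {dsa}")
                low, high = float(dsa[0]), float(dsa[1])
                if not (low <= base <= high) and not node.get("allow_nonbracketing"):
                    raise ParameterError(
                        f"dsa range for {path!r} does not bracket the base value "
                        f"({low} <= {base} <= {high} fails); set allow_nonbracketing "
                        "to keep a printed-inconsistent range")
            else:
                low = high = float(base)
            dist = node.get("psa")
            if dist not in (None, "beta", "gamma", "lognormal", "fixed"):
                raise ParameterError(f"unknown psa distribution for {path!r}: {dist}")
            if dist == "fixed":
                dist = None
        else:
            base = node
            low = high = float(node)
            dist = None
            explicit = False
        base = float(base)
        self.registry[path] = UncertainParam(path, base, low, high, dist, explicit)
        if path in self.overrides:
            self.unused.discard(path)
            return float(self.overrides[path])
        return base

    def raw(self, path: str, default=None):
        try:
            return _dig(self.cfg, path)
        except ParameterError:
            if default is not None:
                return default
            raise


def build_parameter_set(cfg: Mapping, life_table: LifeTable,
                        overrides: Mapping[str, float] | None = None) -> ParameterSet:
    """Assemble and validate a :class:`ParameterSet` from a raw config mapping."""
    b = _Builder(cfg, overrides or {})

    model = cfg.get("model", {})
    settings = ModelSettings(
        cycle_length=float(model.get("cycle_length_years", 0.25)),
        horizon=float(model.get("horizon_years", 30.0)),
        discount_rate=float(model.get("discount_rate", 0.03)),
        wtp_threshold=float(model.get("wtp_threshold", 22000.0)),
        half_cycle_correction=bool(model.get("half_cycle_correction", False)),
        rate_conversion=str(model.get("rate_conversion", "exponential")),
        off_treatment_risk_multiplier=model.get("off_treatment_risk_multiplier"),
        discontinue_after_events=tuple(model.get("discontinue_after_events",
                                                 ["major_is", "ich"])),
    )

    rates = ClinicalRates(
        is_rate=b.value("clinical_rates.is"),
        gi_rate=b.value("clinical_rates.gi"),
        ich_rate=b.value("clinical_rates.ich"),
        mi_rate=b.value("clinical_rates.mi"),
        minor_is_fraction=b.value("clinical_rates.minor_is_fraction"),
    )

    cl = settings.cycle_length
    form = settings.rate_conversion
    p_is = rate_to_cycle_probability(rates.is_rate, cl, form)
    derived = {
        "minor_is": rates.minor_is_fraction * p_is,
        "major_is": (1.0 - rates.minor_is_fraction) * p_is,
        "mi": rate_to_cycle_probability(rates.mi_rate, cl, form),
        "gi": rate_to_cycle_probability(rates.gi_rate, cl, form),
        "ich": rate_to_cycle_probability(rates.ich_rate, cl, form),
    }
    cycle_probs = CycleProbabilities(**{
        k: b.value(f"cycle_probabilities.{k}", derived_base=derived[k])
        for k in derived
    })

    treatments: dict[str, TreatmentProfile] = {}
    for name in b.raw("treatments"):
        prefix = f"treatments.{name}"
        profile = TreatmentProfile(
            name=name,
            daily_drug_cost=b.value(f"{prefix}.daily_drug_cost"),
            hr_is=b.value(f"{prefix}.hr.is", default=1.0),
            hr_mi=b.value(f"{prefix}.hr.mi", default=1.0),
            hr_gi=b.value(f"{prefix}.hr.gi", default=1.0),
            hr_ich=b.value(f"{prefix}.hr.ich", default=1.0),
            hr_discontinuation=b.value(f"{prefix}.hr.discontinuation", default=1.0),
            switch_proportion=b.value(f"{prefix}.switch_proportion"),
            admin_cost_per_cycle=b.value(f"{prefix}.admin_cost_per_cycle"),
            vka_class=bool(b.raw(f"{prefix}.vka_class", default=(name == "vka"))),
        )
        treatments[name] = profile
    if "vka" not in treatments:
        raise ParameterError("configuration must define a 'vka' reference arm")
    vka = treatments["vka"]
    for hr_name in ("hr_is", "hr_mi", "hr_gi", "hr_ich", "hr_discontinuation"):
        if getattr(vka, hr_name) != 1.0:
            raise ParameterError(f"treatments.vka.{hr_name} must be exactly 1")

    disc = DiscontinuationSchedule(probs=(
        b.value("discontinuation.p_0_3m"),
        b.value("discontinuation.p_3_6m"),
        b.value("discontinuation.p_6_12m"),
        b.value("discontinuation.p_12plus"),
    ))

    mortality = MortalityInputs(
        cf_minor_is=b.value("mortality.acute_case_fatality.minor_is"),
        cf_major_is=b.value("mortality.acute_case_fatality.major_is"),
        cf_mi=b.value("mortality.acute_case_fatality.mi"),
        cf_ich=b.value("mortality.acute_case_fatality.ich"),
        cf_gi=b.value("mortality.acute_case_fatality.gi"),
        excess_post_major_is=b.value("mortality.post_excess_per_cycle.post_major_is"),
        excess_post_mi=b.value("mortality.post_excess_per_cycle.post_mi"),
        excess_post_ich=b.value("mortality.post_excess_per_cycle.post_ich"),
        life_table=life_table,
    )

    utilities = UtilitySet(**{
        k: b.value(f"utilities.{k}")
        for k in ("stable_af", "minor_is", "major_is", "post_minor_is",
                  "post_major_is", "mi", "post_mi", "ich", "post_ich", "gi")
    })

    costs = CostSet(
        acute_minor_is=b.value("costs.acute.minor_is"),
        acute_major_is=b.value("costs.acute.major_is"),
        acute_mi=b.value("costs.acute.mi"),
        acute_gi=b.value("costs.acute.gi"),
        acute_ich=b.value("costs.acute.ich"),
        monthly_minor_is=b.value("costs.monthly_followup.minor_is"),
        monthly_major_is=b.value("costs.monthly_followup.major_is"),
        monthly_mi=b.value("costs.monthly_followup.mi"),
        monthly_bleeding=b.value("costs.monthly_followup.bleeding"),
        rehab_is=b.value("costs.rehabilitation.is"),
        rehab_bleeding=b.value("costs.rehabilitation.bleeding"),
        rehab_prop_minor_is=b.value("costs.rehab_proportion.minor_is"),
        rehab_prop_major_is=b.value("costs.rehab_proportion.major_is"),
        rehab_prop_gi=b.value("costs.rehab_proportion.gi"),
        rehab_prop_ich=b.value("costs.rehab_proportion.ich"),
    )

    age_rows = b.raw("age_stroke_rr")
    if not isinstance(age_rows, list) or not age_rows:
        raise ParameterError("age_stroke_rr must be a non-empty list of bands")
    try:
        age_risk = AgeRiskTable(
            band_starts=tuple(int(r["age_from"]) for r in age_rows),
            relative_risks=tuple(float(r["rr"]) for r in age_rows),
        )
    except (KeyError, TypeError) as exc:
        raise ParameterError(f"malformed age_stroke_rr row: {exc}") from None

    cohort_cfg = b.raw("cohort")
    cohort = CohortSpec(
        entry_age=float(cohort_cfg["entry_age"]),
        male_fraction=float(cohort_cfg.get("male_fraction", 0.5)),
        cha2ds2vasc_high_fraction=float(cohort_cfg.get("cha2ds2vasc_high_fraction", 1.0)),
    )

    if b.unused:
        raise ParameterError(f"unknown override parameter ids: {sorted(b.unused)}")

    return ParameterSet(
        clinical_rates=rates,
        cycle_probabilities=cycle_probs,
        treatments=treatments,
        discontinuation=disc,
        mortality=mortality,
        utilities=utilities,
        costs=costs,
        age_risk=age_risk,
        cohort=cohort,
        settings=settings,
        uncertain=b.registry,
        _config=_deep_copy(dict(cfg)),
        _overrides=dict(overrides or {}),
    )


def default_config_path() -> Path:
    return Path(resources.files("nvaf_cea").joinpath("data/default_parameters.yaml"))


def default_life_table_path() -> Path:
    return Path(resources.files("nvaf_cea").joinpath("data/life_table_synthetic.csv"))


def load_parameters(path=None, life_table=None,
                    overrides: Mapping[str, float] | None = None) -> ParameterSet:
    """Load a parameter config (YAML) plus a life table into a ParameterSet.

    With no arguments the packaged defaults are used: the base-case input
    tables of the Spanish real-world analysis and a synthetic (Gompertz)
    life table calibrated to emulate elderly Spanish background mortality.
    """
    cfg_path = Path(path) if path is not None else default_config_path()
    try:
        with open(cfg_path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ParameterError(f"parameter config not found: {cfg_path}") from None
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {cfg_path}: {exc}") from None
    if not isinstance(cfg, dict):
        raise ParameterError(f"{cfg_path} did not parse to a mapping")
    if life_table is None:
        lt = read_life_table(default_life_table_path())
    elif isinstance(life_table, LifeTable):
        lt = life_table
    else:
        lt = read_life_table(life_table)
    return build_parameter_set(cfg, lt, overrides=overrides)
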