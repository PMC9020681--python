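"""Sensitivity and scenario analyses.

Deterministic one-way sensitivity (tornado): every input carrying a printed
range is set to its low and high bound in turn, both arms are re-run and the
ICER spread recorded.

Probabilistic sensitivity analysis: every input tagged with a sampling family
is drawn from a distribution fitted by the method of moments, with the printed
range read as a 95% interval (divisor 3.92):

* probabilities, proportions and utilities -> beta with matching mean and SD;
* costs -> gamma with matching mean and SD;
* hazard ratios -> lognormal with median at the base value and the log-SD
  from the range read as a 95% CI (a literal mode that rescales a beta onto
  [low, high] is available for audit; a [0, 1] beta cannot represent hazard
  ratios above 1).

Draws are independent across parameters.  The cost-effectiveness
acceptability curve (CEAC) reports, per willingness-to-pay threshold, the
fraction of draws with positive net monetary benefit versus VKA.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ArmResult, Incremental, compare_arms, run_cohort
from .parameters import ParameterError, ParameterSet, UncertainParam

__all__ = [
    "DistributionSpec", "fit_beta_from_range", "fit_gamma_from_range",
    "fit_lognormal_from_range", "fit_distribution",
    "DSAEntry", "tornado",
    "PSASample", "PSAResult", "CEACCurve", "run_psa",
    "SCENARIOS", "run_scenario", "ScenarioResult",
]

log = logging.getLogger(__name__)

#: Printed ranges are read as 95% intervals: SD = (high - low) / 3.92.
RANGE_TO_SD = 3.92


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter."""

    kind: str                 # "point", "beta", "gamma", "lognormal", "scaled_beta"
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "point":
            (v,) = self.params
            return v if size is None else np.full(size, v)
        if self.kind == "beta":
            a, b = self.params
            return rng.beta(a, b, size=size)
        if self.kind == "gamma":
            shape, scale = self.params
            return rng.gamma(shape, scale, size=size)
        if self.kind == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size=size)
        if self.kind == "scaled_beta":
            a, b, low, high = self.params
            return low + (high - low) * rng.beta(a, b, size=size)
        raise ParameterError(f"unknown distribution kind {self.kind!r}")

    @property
    def mean(self) -> float:
        if self.kind == "point":
            return self.params[0]
        if self.kind == "beta":
            a, b = self.params
            return a / (a + b)
        if self.kind == "gamma":
            shape, scale = self.params
            return shape * scale
        if self.kind == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma ** 2 / 2.0)
        if self.kind == "scaled_beta":
            a, b, low, high = self.params
            return low + (high - low) * a / (a + b)
        raise ParameterError(f"unknown distribution kind {self.kind!r}")


def _beta_moments(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        warnings.warn(
            f"beta moments infeasible (mean {mean}, sd {sd}); "
            "falling back to the flattest beta with alpha, beta >= 1")
        nu = 1.0 / min(mean, 1.0 - mean)
    else:
        nu = limit / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_beta_from_range(base: float, low: float, high: float,
                        sd_scale: float = 1.0) -> DistributionSpec:
    """Beta with mean ``base`` and SD ``(high - low) / 3.92`` (moments fit)."""
    if not 0.0 < base < 1.0:
        raise ParameterError(f"beta base value must be in (0, 1), got {base}")
    sd = (high - low) / RANGE_TO_SD * sd_scale
    if sd <= 0.0:
        return DistributionSpec("point", (base,))
    a, b = _beta_moments(base, sd)
    return DistributionSpec("beta", (a, b))


def fit_gamma_from_range(base: float, low: float, high: float,
                         sd_scale: float = 1.0) -> DistributionSpec:
    """Gamma with mean ``base`` and SD ``(high - low) / 3.92``."""
    if base <= 0.0:
        raise ParameterError(f"gamma base value must be > 0, got {base}")
    if low >= high:
        if low > high:
            warnings.warn(f"degenerate gamma range [{low}, {high}]; using a point mass")
        return DistributionSpec("point", (base,))
    sd = (high - low) / RANGE_TO_SD * sd_scale
    if sd <= 0.0:
        return DistributionSpec("point", (base,))
    shape = (base / sd) ** 2
    scale = sd * sd / base
    return DistributionSpec("gamma", (shape, scale))


def fit_lognormal_from_range(base: float, low: float, high: float,
                             sd_scale: float = 1.0) -> DistributionSpec:
    """Lognormal with median ``base``; log-SD from the range read as a 95% CI."""
    if base <= 0.0 or low <= 0.0 or high <= 0.0:
        raise ParameterError(
            f"lognormal fit needs positive base/low/high, got {base}, {low}, {high}")
    sigma = (math.log(high) - math.log(low)) / RANGE_TO_SD * sd_scale
    if sigma <= 0.0:
        return DistributionSpec("point", (base,))
    return DistributionSpec("lognormal", (math.log(base), sigma))


def _scaled_beta_from_range(base: float, low: float, high: float,
                            sd_scale: float = 1.0) -> DistributionSpec:
    """Audit mode for hazard ratios: a beta rescaled onto [low, high]."""
    if low >= high:
        return DistributionSpec("point", (base,))
    m = (base - low) / (high - low)
    m = min(max(m, 1e-6), 1.0 - 1e-6)
    sd = sd_scale / RANGE_TO_SD  # unit-interval SD of the rescaled range
    if sd <= 0.0:
        return DistributionSpec("point", (base,))
    a, b = _beta_moments(m, sd)
    return DistributionSpec("scaled_beta", (a, b, low, high))


def fit_distribution(spec: UncertainParam, sd_scale: float = 1.0,
                     hr_mode: str = "lognormal") -> DistributionSpec:
    """Fit the sampling distribution for one registry entry."""
    if spec.dist is None or not spec.explicit_range or spec.low >= spec.high:
        return DistributionSpec("point", (spec.base,))
    if spec.dist == "beta":
        return fit_beta_from_range(spec.base, spec.low, spec.high, sd_scale)
    if spec.dist == "gamma":
        return fit_gamma_from_range(spec.base, spec.low, spec.high, sd_scale)
    if spec.dist == "lognormal":
        if hr_mode == "scaled_beta":
            return _scaled_beta_from_range(spec.base, spec.low, spec.high, sd_scale)
        return fit_lognormal_from_range(spec.base, spec.low, spec.high, sd_scale)
    raise ParameterError(f"unknown distribution tag {spec.dist!r} for {spec.id}")


# ---------------------------------------------------------------------------
# deterministic (one-way) sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSAEntry:
    """One tornado bar: a parameter at its low and high bound."""

    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None

    @property
    def spread(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.nan
        return abs(self.icer_high - self.icer_low)


def _icer(params: ParameterSet, comparator: str) -> float | None:
    _, ref = run_cohort(params, "vka")
    _, cmp_res = run_cohort(params, comparator)
    return compare_arms(ref, cmp_res).icer_qaly


def tornado(params: ParameterSet, arm: str) -> tuple[list[DSAEntry], float | None]:
    """One-way sensitivity of the ``arm`` vs VKA ICER over every ranged input.

    Both arms are re-run with each parameter at its low and then high bound,
    everything else at base.  Returns the entries sorted by descending ICER
    spread together with the base-case ICER.
    """
    if arm not in params.treatments or arm == "vka":
        raise ParameterError(f"tornado needs a non-VKA comparator arm, got {arm!r}")
    base_icer = _icer(params, arm)
    entries: list[DSAEntry] = []
    for pid, spec in params.uncertain.items():
        if not spec.in_dsa:
            continue
        # inputs specific to another comparator cannot move this comparison
        if pid.startswith("treatments.") and pid.split(".")[1] not in ("vka", arm):
            continue
        try:
            icer_lo = _icer(params.with_overrides({pid: spec.low}), arm)
            icer_hi = _icer(params.with_overrides({pid: spec.high}), arm)
        except ParameterError as exc:
            log.warning("skipping %s in DSA: %s", pid, exc)
            continue
        entries.append(DSAEntry(pid, spec.low, spec.high, icer_lo, icer_hi))
    entries.sort(key=lambda e: (math.isnan(e.spread), -e.spread if not math.isnan(e.spread) else 0.0))
    return entries, base_icer


def tornado_frame(entries: Sequence[DSAEntry], base_icer: float | None) -> pd.DataFrame:
    """Plot-ready tornado export (one row per parameter)."""
    return pd.DataFrame({
        "parameter": [e.parameter for e in entries],
        "low": [e.low for e in entries],
        "high": [e.high for e in entries],
        "icer_low": [e.icer_low for e in entries],
        "icer_high": [e.icer_high for e in entries],
        "spread": [e.spread for e in entries],
        "base_icer": base_icer,
    })


# ---------------------------------------------------------------------------
# probabilistic sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASample:
    """One PSA draw: parameter overrides and incremental outcomes vs VKA."""

    draw: int
    overrides: Mapping[str, float]
    incrementals: Mapping[str, Incremental]


@dataclass(frozen=True)
class CEACCurve:
    """Probability of cost-effectiveness vs VKA on a willingness-to-pay grid."""

    thresholds: np.ndarray                  # euros per QALY
    probabilities: Mapping[str, np.ndarray]  # arm -> prob per threshold

    def at(self, arm: str, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - wtp)))
        return float(self.probabilities[arm][i])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, probs in self.probabilities.items():
            for lam, p in zip(self.thresholds, probs):
                rows.append({"wtp": float(lam), "arm": arm, "probability": float(p)})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PSAResult:
    samples: list[PSASample]
    ceac: CEACCurve
    seed: int
    arms: tuple[str, ...] = field(default_factory=tuple)

    def scatter_frame(self) -> pd.DataFrame:
        """Plot-ready incremental cost-effectiveness plane data."""
        rows = []
        for s in self.samples:
            for arm, inc in s.incrementals.items():
                rows.append({"draw": s.draw, "arm": arm,
                             "delta_cost": inc.delta_cost,
                             "delta_qaly": inc.delta_qaly})
        return pd.DataFrame(rows)


def run_psa(params: ParameterSet, n_draws: int, seed: int,
            wtp_grid: Sequence[float] | None = None,
            sd_scale: float = 1.0, hr_mode: str = "lognormal") -> PSAResult:
    """Monte-Carlo parameter uncertainty analysis.

    Per draw, every tagged parameter is sampled from its fitted distribution,
    all arms are re-run and incremental outcomes versus VKA recorded.  The
    CEAC reports, per threshold ``lambda``, the fraction of draws in which
    ``lambda * dQALY - dCost > 0`` (the net-monetary-benefit rule).
    Reproducible given ``seed``.
    """
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 60000.0, 61)
    thresholds = np.asarray(wtp_grid, dtype=float)
    rng = np.random.default_rng(seed)
    sampled = [(pid, fit_distribution(spec, sd_scale=sd_scale, hr_mode=hr_mode))
               for pid, spec in params.uncertain.items() if spec.in_psa]
    comparators = params.comparator_names
    samples: list[PSASample] = []
    for d in range(n_draws):
        overrides = {pid: float(dist.sample(rng)) for pid, dist in sampled}
        drawn = params.with_overrides(overrides)
        _, ref = run_cohort(drawn, "vka")
        incs = {}
        for arm in comparators:
            _, res = run_cohort(drawn, arm)
            incs[arm] = compare_arms(ref, res)
        samples.append(PSASample(draw=d, overrides=overrides, incrementals=incs))

    probs: dict[str, np.ndarray] = {}
    for arm in comparators:
        dq = np.array([s.incrementals[arm].delta_qaly for s in samples])
        dc = np.array([s.incrementals[arm].delta_cost for s in samples])
        nmb = thresholds[:, None] * dq[None, :] - dc[None, :]
        probs[arm] = (nmb > 0).mean(axis=1)
    ceac = CEACCurve(thresholds=thresholds, probabilities=probs)
    return PSAResult(samples=samples, ceac=ceac, seed=seed, arms=comparators)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

SCENARIOS = ("base", "older_population", "horizon_10", "horizon_20",
             "horizon_30", "alternative_hr")


@dataclass(frozen=True)
class ScenarioResult:
    scenario: str
    results: Mapping[str, ArmResult]
    incrementals: Mapping[str, Incremental]

    def icer_table(self) -> pd.Series:
        return pd.Series({arm: inc.icer_qaly for arm, inc in self.incrementals.items()},
                         name=self.scenario)


def run_scenario(params: ParameterSet, scenario: str,
                 hr_table: Mapping[str, Mapping[str, float]] | None = None) -> ScenarioResult:
    """Run one published scenario analysis.

    ``older_population`` moves cohort entry to age 77; ``horizon_10`` /
    ``horizon_20`` shorten the time horizon; ``alternative_hr`` applies a
    user-supplied hazard-ratio table (``{arm: {event: hr}}``) — the published
    alternative effect sizes are not printed, so they must be provided.
    """
    if scenario not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {scenario!r}; valid scenarios: {list(SCENARIOS)}")
    if scenario in ("base", "horizon_30"):
        p = params
    elif scenario == "older_population":
        p = params.with_settings(entry_age=77.0)
    elif scenario == "horizon_10":
        p = params.with_settings(horizon_years=10.0)
    elif scenario == "horizon_20":
        p = params.with_settings(horizon_years=20.0)
    else:  # alternative_hr
        if not hr_table:
            raise ParameterError(
                "scenario 'alternative_hr' needs a hazard-ratio table "
                "({arm: {event: hr}}); none was supplied")
        p = params.with_hazard_ratios(hr_table)
    results = {name: run_cohort(p, name)[1] for name in p.arm_names}
    ref = results["vka"]
    incs = {arm: compare_arms(ref, results[arm]) for arm in p.comparator_names}
    return ScenarioResult(scenario=scenario, results=results, incrementals=incs)
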