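"""Distribution fitting, tornado, PSA/CEAC and scenario analyses."""

import math

import numpy as np
import pytest

from nvaf_cea.engine import compare_arms, run_cohort
from nvaf_cea.parameters import ParameterError, build_parameter_set
from nvaf_cea.sensitivity import (
    fit_beta_from_range,
    fit_distribution,
    fit_gamma_from_range,
    fit_lognormal_from_range,
    run_psa,
    run_scenario,
    tornado,
    tornado_frame,
)

from conftest import collapse_ranges


class TestBetaFit:
    def test_moment_match_example(self):
        # discontinuation 0-3 months: mean 0.15, range [0.1419, 0.1581]
        spec = fit_beta_from_range(0.15, 0.1419, 0.1581)
        sd = (0.1581 - 0.1419) / 3.92
        assert sd == pytest.approx(0.004133, abs=1e-6)
        nu = 0.15 * 0.85 / sd ** 2 - 1
        a, b = spec.params
        assert a == pytest.approx(0.15 * nu, rel=1e-9)
        assert a == pytest.approx(1119.6, rel=1e-3)
        assert spec.mean == pytest.approx(0.15, rel=1e-9)

    def test_zero_spread_is_point_mass(self):
        spec = fit_beta_from_range(0.5, 0.5, 0.5)
        assert spec.kind == "point"
        rng = np.random.default_rng(0)
        assert spec.sample(rng) == 0.5

    def test_infeasible_moments_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="infeasible"):
            spec = fit_beta_from_range(0.02, 0.0, 0.9)
        a, b = spec.params
        assert min(a, b) >= 1.0

    def test_samples_in_unit_interval(self):
        spec = fit_beta_from_range(0.374, 0.3179, 0.4301)
        x = spec.sample(np.random.default_rng(1), size=2000)
        assert np.all((x > 0) & (x < 1))

    def test_base_outside_unit_interval_rejected(self):
        with pytest.raises(ParameterError):
            fit_beta_from_range(1.5, 1.0, 2.0)


class TestGammaFit:
    def test_moment_match_example(self):
        # acute minor stroke cost: mean 5258, range [3953, 6572]
        spec = fit_gamma_from_range(5258, 3953, 6572)
        sd = (6572 - 3953) / 3.92
        assert sd == pytest.approx(668.1, abs=0.1)
        shape, scale = spec.params
        assert shape == pytest.approx((5258 / sd) ** 2, rel=1e-9)
        assert shape == pytest.approx(61.94, abs=0.05)
        assert spec.mean == pytest.approx(5258, rel=1e-9)

    def test_degenerate_range_warns_to_point(self):
        with pytest.warns(UserWarning, match="degenerate"):
            spec = fit_gamma_from_range(100.0, 50.0, 40.0)
        assert spec.kind == "point"

    def test_samples_strictly_positive(self):
        spec = fit_gamma_from_range(191, 143, 238)
        x = spec.sample(np.random.default_rng(2), size=2000)
        assert np.all(x > 0)


class TestLognormalFit:
    def test_median_at_base(self):
        spec = fit_lognormal_from_range(1.22, 1.12, 1.33)
        mu, sigma = spec.params
        assert math.exp(mu) == pytest.approx(1.22)
        assert sigma == pytest.approx((math.log(1.33) - math.log(1.12)) / 3.92)
        x = spec.sample(np.random.default_rng(3), size=4001)
        assert np.median(x) == pytest.approx(1.22, rel=0.02)

    def test_supports_hazard_ratios_above_one(self):
        x = fit_lognormal_from_range(1.22, 1.12, 1.33).sample(
            np.random.default_rng(4), size=1000)
        assert np.all(x > 0)
        assert x.max() > 1.0

    def test_scaled_beta_audit_mode(self, params):
        spec = params.uncertain["treatments.rivaroxaban.hr.gi"]
        dist = fit_distribution(spec, hr_mode="scaled_beta")
        assert dist.kind == "scaled_beta"
        x = dist.sample(np.random.default_rng(5), size=2000)
        assert np.all((x >= 1.12) & (x <= 1.33))


class TestParameterRecovery:
    def test_sample_means_recover_base_values(self, params):
        """Means of beta/gamma draws and medians of lognormal draws converge."""
        rng = np.random.default_rng(42)
        n = 5000
        checked = 0
        for spec in params.uncertain.values():
            if not spec.in_psa:
                continue
            dist = fit_distribution(spec)
            x = np.asarray(dist.sample(rng, size=n), dtype=float)
            se = x.std(ddof=1) / np.sqrt(n)
            if spec.dist == "lognormal":
                # parameterised by the median; compare a robust location
                assert abs(np.median(x) - spec.base) < 4 * 1.2533 * se + 1e-12
            else:
                assert abs(x.mean() - spec.base) < 4 * se + 1e-12
            checked += 1
        assert checked > 40


class TestTornado:
    def test_collapsed_ranges_give_zero_spread(self, raw_config, params):
        cfg = collapse_ranges(raw_config)
        p = build_parameter_set(cfg, params.mortality.life_table)
        entries, base_icer = tornado(p, "rivaroxaban")
        assert entries, "collapsed config should still enumerate ranged inputs"
        for e in entries:
            assert e.spread == pytest.approx(0.0, abs=1e-6)
            assert e.icer_low == pytest.approx(base_icer, rel=1e-9)

    def test_entries_sorted_by_spread_and_isolated(self, params):
        entries, base_icer = tornado(params, "rivaroxaban")
        spreads = [e.spread for e in entries if not math.isnan(e.spread)]
        assert spreads == sorted(spreads, reverse=True)
        names = {e.parameter for e in entries}
        # inputs specific to other comparators must not enter this tornado
        assert not any(n.startswith("treatments.dabigatran") for n in names)
        assert not any(n.startswith("treatments.apixaban") for n in names)
        assert "treatments.rivaroxaban.hr.is" in names
        # published qualitative drivers: major-stroke mortality and follow-up
        # cost rank in the top half of the tornado
        top_half = [e.parameter for e in entries[:len(entries) // 2]]
        assert "mortality.acute_case_fatality.major_is" in top_half
        assert "costs.monthly_followup.major_is" in top_half
        df = tornado_frame(entries, base_icer)
        assert list(df.columns) == ["parameter", "low", "high", "icer_low",
                                    "icer_high", "spread", "base_icer"]

    def test_requires_comparator_arm(self, params):
        with pytest.raises(ParameterError):
            tornado(params, "vka")


class TestPSA:
    def test_degenerate_draws_reproduce_base_case(self, params):
        res = run_psa(params, n_draws=1, seed=7, sd_scale=0.0)
        _, ref = run_cohort(params, "vka")
        for arm in params.comparator_names:
            _, r = run_cohort(params, arm)
            base = compare_arms(ref, r)
            inc = res.samples[0].incrementals[arm]
            assert inc.delta_cost == pytest.approx(base.delta_cost, abs=1e-9)
            assert inc.delta_qaly == pytest.approx(base.delta_qaly, abs=1e-12)

    def test_same_seed_bit_identical(self, params):
        a = run_psa(params, n_draws=4, seed=11)
        b = run_psa(params, n_draws=4, seed=11)
        assert a.scatter_frame().equals(b.scatter_frame())
        c = run_psa(params, n_draws=4, seed=12)
        assert not a.scatter_frame().equals(c.scatter_frame())

    def test_ceac_definition_at_zero_threshold(self, params):
        res = run_psa(params, n_draws=30, seed=3)
        dc = np.array([s.incrementals["rivaroxaban"].delta_cost for s in res.samples])
        assert res.ceac.at("rivaroxaban", 0.0) == pytest.approx((dc < 0).mean())

    def test_ceac_monotone_for_costlier_more_effective_arm(self, params):
        res = run_psa(params, n_draws=40, seed=5)
        probs = res.ceac.probabilities["rivaroxaban"]
        # monotone non-decreasing over the threshold grid
        assert np.all(np.diff(probs) >= -1e-12)

    def test_draws_respect_supports(self, params):
        res = run_psa(params, n_draws=10, seed=9)
        for s in res.samples:
            for pid, v in s.overrides.items():
                spec = params.uncertain[pid]
                if spec.dist == "beta":
                    assert 0.0 < v < 1.0, pid
                else:
                    assert v > 0.0, pid


class TestScenarios:
    def test_base_alias_reproduces_base_case(self, params):
        base = run_scenario(params, "base")
        again = run_scenario(params, "horizon_30")
        for arm in params.comparator_names:
            assert again.incrementals[arm].icer_qaly == pytest.approx(
                base.incrementals[arm].icer_qaly, rel=1e-12)

    def test_short_horizon_raises_icer(self, params):
        base = run_scenario(params, "base")
        h10 = run_scenario(params, "horizon_10")
        h20 = run_scenario(params, "horizon_20")
        for arm in ("rivaroxaban", "dabigatran"):
            assert h10.incrementals[arm].icer_qaly > base.incrementals[arm].icer_qaly
            assert h20.incrementals[arm].icer_qaly > base.incrementals[arm].icer_qaly

    def test_older_population_raises_icer(self, params):
        base = run_scenario(params, "base")
        older = run_scenario(params, "older_population")
        assert older.results["vka"].life_years < base.results["vka"].life_years
        assert (older.incrementals["rivaroxaban"].icer_qaly
                > base.incrementals["rivaroxaban"].icer_qaly)

    def test_alternative_hr_requires_table(self, params):
        with pytest.raises(ParameterError, match="alternative_hr"):
            run_scenario(params, "alternative_hr")
        hr = {"rivaroxaban": {"is": 0.70, "ich": 0.60}}
        res = run_scenario(params, "alternative_hr", hr_table=hr)
        base = run_scenario(params, "base")
        assert (res.incrementals["rivaroxaban"].delta_qaly
                > base.incrementals["rivaroxaban"].delta_qaly)

    def test_unknown_scenario_lists_valid_names(self, params):
        with pytest.raises(ParameterError, match="valid scenarios"):
            run_scenario(params, "horizon_5")
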