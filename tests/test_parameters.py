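"""Input model: conversions, lookups, fixture fidelity and validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nvaf_cea.parameters import (
    AgeRiskTable,
    DiscontinuationSchedule,
    LifeTable,
    ParameterError,
    age_relative_risk,
    apply_hazard_ratio,
    build_parameter_set,
    cycle_probability_to_rate,
    discontinuation_probability,
    rate_to_cycle_probability,
    read_life_table,
)


class TestRateConversion:
    @pytest.mark.parametrize("rate, expected", [
        (1.04, 1 - math.exp(-1.04 / 400)),   # GI bleeding -> 0.260%
        (0.34, 1 - math.exp(-0.34 / 400)),   # ICH -> 0.085%
        (1.11, 1 - math.exp(-1.11 / 400)),   # ischaemic stroke -> 0.277%
        (0.0, 0.0),
    ])
    def test_exponential_form(self, rate, expected):
        assert rate_to_cycle_probability(rate, 0.25) == pytest.approx(expected, rel=1e-12)

    def test_printed_precision(self):
        # the published 3-month probabilities, in percent to 3 decimals
        assert round(100 * rate_to_cycle_probability(1.04, 0.25), 3) == 0.260
        assert round(100 * rate_to_cycle_probability(0.34, 0.25), 3) == 0.085

    def test_linear_form_for_audit(self):
        assert rate_to_cycle_probability(1.04, 0.25, form="linear") == pytest.approx(0.0026)

    @pytest.mark.parametrize("rate, cl", [(-0.1, 0.25), (1.0, 0.0), (1.0, -1.0)])
    def test_invalid_inputs(self, rate, cl):
        with pytest.raises(ParameterError):
            rate_to_cycle_probability(rate, cl)

    def test_inverse_examples(self):
        assert cycle_probability_to_rate(0.0, 0.25) == 0.0
        p = rate_to_cycle_probability(1.04, 0.25)
        assert cycle_probability_to_rate(p, 0.25) == pytest.approx(1.04, rel=1e-12)
        with pytest.raises(ParameterError):
            cycle_probability_to_rate(1.0, 0.25)

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_property(self, rate):
        p = rate_to_cycle_probability(rate, 0.25)
        assert cycle_probability_to_rate(p, 0.25) == pytest.approx(rate, rel=1e-12, abs=1e-12)

    @given(st.floats(min_value=0.0, max_value=49.0), st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_rate(self, rate, cl):
        assert (rate_to_cycle_probability(rate + 1.0, cl)
                > rate_to_cycle_probability(rate, cl))


class TestHazardRatio:
    def test_identity_and_limit(self):
        assert apply_hazard_ratio(0.0026, 1.0) == pytest.approx(0.0026, rel=1e-15)
        assert apply_hazard_ratio(0.5, 1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_agrees_with_rate_domain_oracle(self):
        # oracle: convert to a rate, scale it, convert back
        p, hr = 0.0026, 1.22
        rate = cycle_probability_to_rate(p, 0.25)
        expected = rate_to_cycle_probability(rate * hr, 0.25)
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, rel=1e-12)
        assert apply_hazard_ratio(p, hr) == pytest.approx(0.0031711, abs=1e-6)

    def test_invalid(self):
        with pytest.raises(ParameterError):
            apply_hazard_ratio(0.5, 0.0)
        with pytest.raises(ParameterError):
            apply_hazard_ratio(1.0, 1.0)

    @given(st.floats(min_value=0.0, max_value=0.99),
           st.floats(min_value=0.05, max_value=5.0),
           st.floats(min_value=0.05, max_value=5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_composition_in_rate_domain(self, p, h1, h2):
        composed = apply_hazard_ratio(p, h1 * h2)
        stepwise = apply_hazard_ratio(apply_hazard_ratio(p, h1), h2)
        assert stepwise == pytest.approx(composed, rel=1e-10, abs=1e-12)


class TestAgeRisk:
    def test_fixture_lookups(self, params):
        t = params.age_risk
        assert age_relative_risk(72, t) == 1.000
        assert age_relative_risk(91, t) == 1.719
        assert age_relative_risk(57, t) == 0.667
        assert age_relative_risk(120, t) == 1.719   # clamp above
        assert age_relative_risk(30, t) == 0.667    # clamp below
        assert age_relative_risk(74.9, t) == 1.000  # floor(74.9) = 74

    def test_fixture_monotone(self, params):
        rrs = params.age_risk.relative_risks
        assert all(a < b for a, b in zip(rrs, rrs[1:]))
        assert rrs[0] == 0.667 and rrs[-1] == 1.719

    def test_non_monotone_rejected(self):
        with pytest.raises(ParameterError):
            AgeRiskTable(band_starts=(55, 60), relative_risks=(1.0, 0.9))


class TestDiscontinuation:
    def test_band_probabilities(self, params):
        s = params.discontinuation
        assert discontinuation_probability(2, s, 1.0) == 0.1500
        assert discontinuation_probability(4, s, 1.0) == 0.1059
        assert discontinuation_probability(8, s, 1.0) == 0.0823
        assert discontinuation_probability(14, s, 1.0) == 0.0640

    def test_hazard_ratio_applied(self, params):
        got = discontinuation_probability(2, params.discontinuation, 0.62)
        assert got == pytest.approx(1 - 0.85 ** 0.62, rel=1e-12)

    def test_negative_months(self, params):
        with pytest.raises(ParameterError):
            discontinuation_probability(-1, params.discontinuation, 1.0)

    def test_band_boundaries_must_increase(self):
        with pytest.raises(ParameterError):
            DiscontinuationSchedule(probs=(0.1, 0.1, 0.1, 0.1),
                                    band_starts_months=(0, 6, 3, 12))


class TestLifeTable:
    def test_cycle_probability(self):
        lt = LifeTable(ages=np.arange(70, 111), qx=np.full(41, 0.04))
        assert lt.cycle_qx(75, 0.25) == pytest.approx(1 - 0.96 ** 0.25, rel=1e-12)

    def test_degenerate_rates(self):
        lt = LifeTable(ages=np.arange(50, 111), qx=np.zeros(61))
        assert lt.cycle_qx(80, 0.25) == 0.0
        qx = np.zeros(61)
        qx[-1] = 1.0
        lt = LifeTable(ages=np.arange(50, 111), qx=qx)
        assert lt.cycle_qx(110, 0.25) == 1.0
        assert lt.cycle_qx(200, 0.25) == 1.0  # clamped to terminal age

    def test_csv_round_trip(self, tmp_path):
        lt = LifeTable(ages=np.arange(60, 100), qx=np.linspace(0.01, 0.5, 40))
        path = tmp_path / "lt.csv"
        lt.to_csv(path)
        back = read_life_table(path)
        assert np.array_equal(back.ages, lt.ages)
        assert np.allclose(back.qx, lt.qx)

    def test_headerless_csv(self, tmp_path):
        path = tmp_path / "lt.csv"
        path.write_text("70,0.02\n71,0.03\n")
        lt = read_life_table(path)
        assert lt.annual_qx(71) == 0.03

    def test_validation(self, tmp_path):
        with pytest.raises(ParameterError):
            LifeTable(ages=np.array([70, 72]), qx=np.array([0.1, 0.2]))
        with pytest.raises(ParameterError):
            LifeTable(ages=np.array([70, 71]), qx=np.array([0.1, 1.2]))
        bad = tmp_path / "bad.csv"
        bad.write_text("age,qx\n70,0.02\nseventy-one,0.03\n")
        with pytest.raises(ParameterError):
            read_life_table(bad)


class TestPackagedFixture:
    def test_printed_inputs_survive_loading(self, params):
        assert params.clinical_rates.gi_rate == 1.04
        assert params.treatments["rivaroxaban"].hr_ich == 0.68
        assert params.treatments["dabigatran"].hr_discontinuation == 0.91
        assert params.treatments["apixaban"].hr_mi == 1.00
        assert params.utilities.post_major_is == 0.56
        assert params.costs.monthly_major_is == 2159
        assert params.costs.rehab_prop_ich == 0.450
        assert params.cohort.entry_age == 73.4
        assert params.settings.wtp_threshold == 22000

    def test_derived_cycle_probabilities_match_printed(self, params):
        cp = params.cycle_probabilities
        # exact at printed precision
        assert round(100 * cp.gi, 3) == 0.260
        assert round(100 * cp.ich, 3) == 0.085
        # minor/major/MI within 0.001 percentage points (printed rounding)
        assert 100 * cp.minor_is == pytest.approx(0.114, abs=1e-3)
        assert 100 * cp.major_is == pytest.approx(0.163, abs=1e-3)
        assert 100 * cp.mi == pytest.approx(0.193, abs=1e-3)

    def test_vka_hazard_ratios_are_unity(self, params):
        vka = params.treatments["vka"]
        assert (vka.hr_is, vka.hr_mi, vka.hr_gi, vka.hr_ich,
                vka.hr_discontinuation) == (1, 1, 1, 1, 1)
        assert vka.vka_class

    def test_uncertainty_registry(self, params):
        reg = params.uncertain
        hr = reg["treatments.rivaroxaban.hr.gi"]
        assert (hr.base, hr.low, hr.high, hr.dist) == (1.22, 1.12, 1.33, "lognormal")
        assert reg["costs.monthly_followup.mi"].base == 516  # flagged non-bracketing
        assert not reg["treatments.vka.daily_drug_cost"].in_dsa
        assert reg["clinical_rates.is"].in_dsa
        assert not reg["clinical_rates.is"].in_psa  # probabilities carry the PSA tag

    def test_life_table_covers_cohort(self, params):
        lt = params.mortality.life_table
        assert lt.min_age <= params.cohort.entry_age
        assert lt.max_age >= 110


class TestValidation:
    def test_switch_proportion_out_of_range(self, config):
        config["treatments"]["rivaroxaban"]["switch_proportion"] = {"value": 1.5}
        with pytest.raises(ParameterError, match="switch_proportion"):
            build_parameter_set(config, zero_lt())

    def test_missing_key_is_named(self, config):
        del config["costs"]["acute"]["ich"]
        with pytest.raises(ParameterError, match="costs.acute.ich"):
            build_parameter_set(config, zero_lt())

    def test_nonbracketing_range_rejected_unless_flagged(self, config):
        config["utilities"]["stable_af"] = {"value": 0.73, "dsa": [0.8, 0.9], "psa": "beta"}
        with pytest.raises(ParameterError, match="utilities.stable_af"):
            build_parameter_set(config, zero_lt())
        config["utilities"]["stable_af"]["allow_nonbracketing"] = True
        build_parameter_set(config, zero_lt())  # now accepted

    def test_unknown_override_rejected(self, params):
        with pytest.raises(ParameterError, match="no.such.parameter"):
            params.with_overrides({"no.such.parameter": 1.0})

    def test_override_changes_value(self, params):
        p2 = params.with_overrides({"utilities.stable_af": 0.70})
        assert p2.utilities.stable_af == 0.70
        assert params.utilities.stable_af == 0.73  # original untouched

    def test_vka_hr_must_be_unity(self, config):
        config["treatments"]["vka"]["hr"]["is"] = 0.9
        with pytest.raises(ParameterError, match="vka"):
            build_parameter_set(config, zero_lt())


def zero_lt():
    ages = np.arange(50, 111)
    return LifeTable(ages=ages, qx=np.zeros_like(ages, dtype=float))
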