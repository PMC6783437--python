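import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mnapport.defaults import default_requirements
from mnapport.errors import ConfigError, DataError
from mnapport.risk import (
    RequirementPolicy,
    build_risk_table,
    convert_rni_to_ear,
    expand_requirements,
    risk_percent,
)
from mnapport.supply import SupplyScenario
from mnapport.units import round_half_up


class TestRniConversion:
    def test_definition(self):
        assert convert_rni_to_ear(1.2, 1.2) == pytest.approx(1.0)
        assert convert_rni_to_ear(0.0262, 1.2) == pytest.approx(0.0218333, abs=1e-6)

    def test_divisor_must_exceed_one(self):
        with pytest.raises(ConfigError):
            convert_rni_to_ear(1.0, 1.0)

    def test_positive_rni_required(self):
        with pytest.raises(DataError):
            convert_rni_to_ear(0.0)


class TestRiskPercent:
    def test_printed_calcium_pair(self):
        assert round_half_up(risk_percent(852, 1200)) == 95
        assert round_half_up(risk_percent(914, 1200)) == 89

    def test_supply_equal_to_requirement_is_half_the_population(self):
        for cv in (0.1, 0.25, 0.5):
            assert risk_percent(5.0, 5.0, cv=cv) == pytest.approx(50.0)

    def test_copper_risk_below_one_percent(self):
        assert risk_percent(3.7, 0.7) < 1.0

    def test_strictly_monotone_in_supply_and_requirement(self):
        # ranges chosen away from the CDF's floating-point saturation
        s = np.linspace(700, 3000, 40)
        r = risk_percent(s, 1200.0)
        assert (np.diff(r) < 0).all()
        ears = np.linspace(500, 1600, 40)
        r2 = risk_percent(800.0, ears)
        assert (np.diff(r2) > 0).all()

    def test_cv_widens_toward_50_from_either_side(self):
        below = risk_percent(800, 1200, cv=0.4)      # S < EAR: more spread, less risk
        assert below < risk_percent(800, 1200, cv=0.2)
        above = risk_percent(1600, 1200, cv=0.4)     # S > EAR: more spread, more risk
        assert above > risk_percent(1600, 1200, cv=0.2)

    def test_small_cv_recovers_the_step_function(self):
        assert risk_percent(999.0, 1000.0, cv=1e-6) == pytest.approx(100.0)
        assert risk_percent(1001.0, 1000.0, cv=1e-6) == pytest.approx(0.0)

    def test_zero_supply_returns_100_by_convention(self, caplog):
        with caplog.at_level("WARNING"):
            assert risk_percent(0.0, 1.0) == 100.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DataError):
            risk_percent(-1.0, 1.0)
        with pytest.raises(DataError):
            risk_percent(1.0, 0.0)

    def test_invalid_cv_rejected(self):
        with pytest.raises(ConfigError):
            risk_percent(1.0, 1.0, cv=1.5)

    def test_monte_carlo_oracle_small(self, rng):
        for _ in range(25):
            S = float(rng.uniform(0.1, 100))
            ear = float(rng.uniform(0.1, 100))
            cv = float(rng.uniform(0.05, 0.5))
            draws = S * (1 + cv * rng.standard_normal(200_000))
            mc = 100.0 * float(np.mean(draws < ear))
            assert risk_percent(S, ear, cv=cv) == pytest.approx(mc, abs=0.6)

    def test_lognormal_variant_is_monotone_and_bounded(self):
        s = np.linspace(10, 200, 30)
        r = risk_percent(s, 60.0, distribution="lognormal")
        assert (np.diff(r) < 0).all()
        assert ((r >= 0) & (r <= 100)).all()


def _scenario(totals, country="Tanzania", scenario="non_calcareous"):
    return SupplyScenario(country=country, scenario=scenario,
                          per_item=pd.DataFrame(), total=totals)


class TestRiskTable:
    def test_requirement_expansion_covers_both_sexes(self):
        reqs = default_requirements()
        ears = expand_requirements(reqs)
        assert set(ears["sex"]) == {"F", "M"}
        assert len(ears) == 16      # 8 elements x 2 sexes

    def test_rni_rows_are_converted(self):
        reqs = pd.DataFrame([{"element": "Zn", "sex": "both",
                              "ear_mg_day": np.nan, "rni_mg_day": 12.0}])
        ears = expand_requirements(reqs)
        np.testing.assert_allclose(ears["ear_mg_day"], 10.0)
        assert (ears["provenance"] == "converted_from_rni").all()

    def test_missing_requirement_names_element_and_sex(self):
        sc = _scenario({"Ca": 852.0, "Cu": 3.7})
        reqs = default_requirements()
        reqs = reqs[reqs.element != "Cu"]
        with pytest.raises(ConfigError, match="Cu"):
            build_risk_table([sc], reqs)

    def test_double_supply_everywhere_keeps_risk_below_3_percent(self):
        reqs = default_requirements()
        ears = expand_requirements(reqs)
        totals = {e: 2.0 * ears[ears.element == e]["ear_mg_day"].max()
                  for e in ears["element"].unique()}
        table = build_risk_table([_scenario(totals)], reqs)
        assert (table["risk_percent"] < 3.0).all()    # Phi(-2) ~ 2.3%

    def test_fixture_country_scenario_sex_grid(self, tiny):
        scs = [_scenario({"Ca": 852.0}),
               _scenario({"Ca": 914.0}, scenario="calcareous")]
        table = build_risk_table(scs, tiny.requirements)
        assert len(table) == 4
        by = table.set_index(["scenario", "sex"])["risk_rounded"]
        assert by.loc[("non_calcareous", "F")] == 95
        assert by.loc[("calcareous", "M")] == 89
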