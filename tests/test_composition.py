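import numpy as np
import pandas as pd
import pytest

from mnapport.composition import (
    aggregate_by_group,
    aggregate_by_item,
    build_published_table,
)
from mnapport.errors import ConfigError, DataError


def test_calcareous_maize_selenium_median(tiny):
    comp = aggregate_by_item(tiny.crops, tiny.soils, "calcareous")
    cell = comp[(comp.country == "Tanzania") & (comp.food_item == "maize")
                & (comp.element == "Se")]
    assert cell["median_mg_kg_dw"].iloc[0] == pytest.approx(0.19)
    assert cell["n"].iloc[0] == 3


def test_single_sample_item_median_equals_that_sample(tiny):
    comp = aggregate_by_item(tiny.crops, tiny.soils, "calcareous")
    cell = comp[(comp.country == "Tanzania") & (comp.food_item == "sukuma_wiki")
                & (comp.element == "Ca")]
    assert cell["median_mg_kg_dw"].iloc[0] == pytest.approx(29569.0)
    assert cell["n"].iloc[0] == 1


def test_scenario_tables_are_disjoint_and_exhaustive(survey):
    calc = aggregate_by_item(survey.crops, survey.soils, "calcareous")
    ncalc = aggregate_by_item(survey.crops, survey.soils, "non_calcareous")
    merged = calc.merge(ncalc, on=["country", "food_item", "element"],
                        how="outer", suffixes=("_c", "_n")).fillna({"n_c": 0, "n_n": 0})
    totals = survey.crops.groupby(["country", "food_item"]).size()
    for (country, item), g in merged.groupby(["country", "food_item"]):
        assert (g["n_c"] + g["n_n"] == totals.loc[(country, item)]).all()


def test_unresolvable_site_is_excluded_with_warning(tiny, caplog):
    crops = tiny.crops.copy()
    crops.loc[0, "site_id"] = "TZ-MISSING"
    with caplog.at_level("WARNING"):
        comp = aggregate_by_item(crops, tiny.soils, "calcareous")
    cell = comp[(comp.food_item == "maize") & (comp.element == "Se")
                & (comp.country == "Tanzania")]
    assert cell["n"].iloc[0] == 2      # the dropped row was a calcareous maize
    assert "does not resolve" in caplog.text


def test_invalid_scenario_rejected(tiny):
    with pytest.raises(ConfigError):
        aggregate_by_item(tiny.crops, tiny.soils, "published")


class TestGroupMedians:
    def _crops(self, values, items):
        n = len(values)
        return pd.DataFrame({
            "sample_id": [f"C{i}" for i in range(n)],
            "country": "Kenya",
            "site_id": "K1",
            "food_item": items,
            "food_group": "vegetables",
            "Zn": values,
        })

    def test_pooled_two_item_group(self):
        crops = self._crops([10.0, 20.0, 30.0, 40.0],
                            ["tomato", "tomato", "onion", "onion"])
        out = aggregate_by_group(crops, soils=None)
        cell = out[out.element == "Zn"]
        assert cell["median_mg_kg_dw"].iloc[0] == pytest.approx(25.0)
        assert cell["n"].iloc[0] == 4

    def test_group_median_within_pooled_range(self, survey):
        out = aggregate_by_group(survey.crops, survey.soils)
        for r in out.itertuples():
            pool = survey.crops[(survey.crops.country == r.country)
                                & (survey.crops.food_group == r.food_group)][r.element]
            assert pool.min() <= r.median_mg_kg_dw <= pool.max()

    def test_unmapped_item_is_a_config_error(self):
        crops = self._crops([10.0], ["tomato"])
        with pytest.raises(ConfigError, match="tomato"):
            aggregate_by_group(crops, soils=None, group_map={"onion": "vegetables"})

    def test_adding_sample_at_median_does_not_move_it(self):
        crops = self._crops([10.0, 20.0, 30.0], ["tomato"] * 3)
        base = aggregate_by_group(crops, soils=None)["median_mg_kg_dw"].iloc[0]
        more = self._crops([10.0, 20.0, 30.0, 20.0], ["tomato"] * 4)
        again = aggregate_by_group(more, soils=None)["median_mg_kg_dw"].iloc[0]
        assert base == again == 20.0


class TestPublishedTable:
    def test_fao_cell_is_measured_and_substitute_fills_gaps(self):
        fao = pd.DataFrame([{"country": "Tanzania", "food_item": "maize",
                             "element": "Se", "median_mg_kg_dw": 0.029}])
        subs = pd.DataFrame([{"country": "Tanzania", "food_item": "maize",
                              "element": "I", "median_mg_kg_dw": 0.004}])
        out = build_published_table(fao, subs)
        se = out[out.element == "Se"].iloc[0]
        io_ = out[out.element == "I"].iloc[0]
        assert se["provenance"] == "measured"
        assert se["median_mg_kg_dw"] == pytest.approx(0.029)
        assert io_["provenance"] == "substituted"
        assert (out["scenario"] == "published").all()

    def test_fao_takes_precedence_over_substitution(self):
        fao = pd.DataFrame([{"country": "Kenya", "food_item": "maize",
                             "element": "Zn", "median_mg_kg_dw": 20.0}])
        subs = pd.DataFrame([{"country": "Kenya", "food_item": "maize",
                              "element": "Zn", "median_mg_kg_dw": 99.0}])
        out = build_published_table(fao, subs)
        assert len(out) == 1
        assert out["median_mg_kg_dw"].iloc[0] == 20.0

    def test_item_missing_everywhere_is_a_hard_error(self):
        fao = pd.DataFrame([{"country": "Kenya", "food_item": "maize",
                             "element": "Zn", "median_mg_kg_dw": 20.0}])
        with pytest.raises(DataError, match="cassava"):
            build_published_table(fao, None, required_items=["maize", "cassava"])
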