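import numpy as np
import pytest

from conftest import lmg_shares_by_enumeration
from mnapport.errors import DataError
from mnapport.lmg import (
    PREDICTOR_SLOTS,
    build_design,
    decompose_design,
    decomposition_report,
    lmg_decompose,
    lmg_shares,
)


def _orthonormal_design(rng, n=32, k=4):
    """Centred orthonormal columns (so marginal R^2s add exactly)."""
    A = rng.standard_normal((n, k))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q


class TestShares:
    def test_orthogonal_predictors_recover_marginal_r2(self, rng):
        Q = _orthonormal_design(rng, k=3)
        x1, x2, resid = Q[:, 0], Q[:, 1], Q[:, 2]
        y = np.sqrt(0.3) * x1 + np.sqrt(0.1) * x2 + np.sqrt(0.6) * resid
        shares, r2 = lmg_shares(np.column_stack([x1, x2]), y)
        assert shares[0] * 100 == pytest.approx(30.0, abs=1e-8)
        assert shares[1] * 100 == pytest.approx(10.0, abs=1e-8)
        assert r2 * 100 == pytest.approx(40.0, abs=1e-8)

    def test_single_predictor_share_equals_total_r2(self, rng):
        X = rng.standard_normal((40, 1))
        y = 0.7 * X[:, 0] + rng.standard_normal(40)
        shares, r2 = lmg_shares(X, y)
        assert shares[0] == pytest.approx(r2, abs=1e-12)

    @pytest.mark.parametrize("p", [2, 3, 4])
    def test_subset_formula_matches_ordering_enumeration(self, rng, p):
        for _ in range(5):
            X = rng.standard_normal((25, p))
            y = X @ rng.uniform(-1, 1, p) + rng.standard_normal(25)
            shares, _ = lmg_shares(X, y)
            oracle = lmg_shares_by_enumeration(X, y)
            np.testing.assert_allclose(shares, oracle, atol=1e-10)

    def test_shares_sum_to_r2_for_correlated_designs(self, rng):
        for _ in range(10):
            p = int(rng.integers(2, 9))
            base = rng.standard_normal((50, p))
            X = base + 0.5 * base[:, [0]]          # induce correlation
            y = X @ rng.uniform(-1, 1, p) + rng.standard_normal(50)
            shares, r2 = lmg_shares(X, y)
            assert shares.sum() == pytest.approx(r2, abs=1e-10)
            assert (shares >= -1e-12).all()

    def test_rank_deficient_design_rejected(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 2] = X[:, 0] + X[:, 1]
        with pytest.raises(DataError, match="rank"):
            lmg_shares(X, rng.standard_normal(30))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(DataError):
            lmg_shares(rng.standard_normal((4, 3)), rng.standard_normal(4))


class TestDecompose:
    def test_strong_predictor_is_dominant_with_correct_direction(self, rng):
        X = rng.standard_normal((150, 5))
        y = -1.2 * X[:, 2] + 0.5 * rng.standard_normal(150)
        res = lmg_decompose(X, y, names=list("abcde"))
        t = res.table
        assert t.loc["c", "dominant"]
        assert t.loc["c", "direction"] == "-"
        assert t["dominant"].sum() == 1
        assert t["share_percent"].sum() == pytest.approx(
            res.total_variance_percent, abs=1e-8)

    def test_no_dominant_flag_without_significance(self, rng):
        # pure noise will usually have no significant predictor; draw until so
        for attempt in range(10):
            X = rng.standard_normal((40, 3))
            y = rng.standard_normal(40)
            res = lmg_decompose(X, y)
            if not res.table["significant"].any():
                assert res.table["dominant"].sum() == 0
                return
        pytest.fail("never sampled an all-insignificant model")


class TestDesign:
    def test_same_element_slot_dedups_named_slot(self, survey):
        d = build_design(survey.crops, survey.soils, "maize", "Ca")
        assert "soil_element" in d.X.columns
        assert "Ca" not in d.X.columns
        assert d.X.shape[1] == 10
        assert d.dropped_slot == "Ca"

    def test_elements_outside_panel_keep_11_slots(self, survey):
        d = build_design(survey.crops, survey.soils, "maize", "Se")
        assert d.X.shape[1] == 11
        assert list(d.X.columns) == list(PREDICTOR_SLOTS)

    def test_complete_pairs_are_preserved(self, survey):
        d = build_design(survey.crops, survey.soils, "maize", "Zn")
        n_maize = (survey.crops.food_group == "maize").sum()
        assert len(d.y) == n_maize
        assert d.n_dropped == 0

    def test_nonpositive_crop_value_dropped_and_counted(self, survey):
        crops = survey.crops.copy()
        first = crops.index[crops.food_group == "maize"][0]
        crops.loc[first, "Se"] = 0.0
        d = build_design(crops, survey.soils, "maize", "Se")
        assert d.n_dropped == 1

    def test_degenerate_when_rows_below_p_plus_2(self, survey):
        crops = survey.crops[survey.crops.food_group == "maize"].head(8)
        d = build_design(crops, survey.soils, "maize", "Se")
        assert d.degenerate
        res = decompose_design(d)
        assert res.degenerate
        assert np.isnan(res.total_variance_percent)

    def test_regression_recovers_the_generating_signal(self, survey):
        # the generator's Se model puts its largest variance fraction on pH
        d = build_design(
            survey.crops[survey.crops.country == "Kenya"],
            survey.soils[survey.soils.country == "Kenya"], "maize", "Se")
        res = decompose_design(d)
        top3 = res.table["share_percent"].nlargest(3).index
        assert "pH" in top3


class TestReport:
    def test_matrix_layout_and_flags(self, survey):
        designs = [build_design(survey.crops, survey.soils, "maize", e)
                   for e in ("Ca", "Se")]
        results = [decompose_design(d) for d in designs]
        rep = decomposition_report(results)
        assert set(rep["predictor"]) == set(PREDICTOR_SLOTS) | {"total_variance"}
        ca = rep.set_index("predictor")["Ca"]
        assert ca.loc["Ca"] == "-"              # deduplicated named slot
        # dominant cell carries ** and totals parse back to floats
        joined = " ".join(rep["Se"].astype(str))
        assert "**" in joined
        float(rep.set_index("predictor").loc["total_variance", "Se"])

    def test_degenerate_column_rendered_blank(self, survey):
        crops = survey.crops[survey.crops.food_group == "maize"].head(8)
        res = decompose_design(build_design(crops, survey.soils, "maize", "Se"))
        rep = decomposition_report([res])
        assert (rep.set_index("predictor").loc["total_variance", "Se"]
                == "degenerate")
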