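import numpy as np
import pandas as pd
import pytest

from barcodekit.morphology import (
    MorphTable,
    default_key_config,
    discriminant_analysis,
    identification_key,
    loo_classification_rate,
    select_dfa_variables,
    standardize_percent_sl,
    summarize_characters,
)


def table_from_groups(values: dict[str, list], column: str = "DP",
                      sl: float = 100.0) -> MorphTable:
    rows = []
    for sp, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                         "SL_mm": sl, column: v})
    return MorphTable(pd.DataFrame(rows))


def brute_force_dfa(X, y):
    """Independent oracle: explicit scatter matrices + dense eigensolve."""
    groups = sorted(set(y))
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Xg = X[np.asarray(y) == g]
        mg = Xg.mean(axis=0)
        for row in Xg:
            d = (row - mg)[:, None]
            W += d @ d.T
        d = (mg - grand)[:, None]
        B += len(Xg) * (d @ d.T)
    evals = np.linalg.eigvals(np.linalg.inv(W) @ B)
    evals = np.sort(np.real(evals))[::-1][: min(len(groups) - 1, p)]
    wilks = np.prod(1.0 / (1.0 + evals))
    return evals, wilks


class TestStandardize:
    def test_direct_arithmetic(self):
        assert standardize_percent_sl(43.4, 200.0) == pytest.approx(21.7)

    def test_identity_case(self):
        assert standardize_percent_sl(57.0, 57.0) == 100.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            standardize_percent_sl(0.0, 100.0)
        with pytest.raises(ValueError):
            standardize_percent_sl(10.0, -1.0)


class TestSummaries:
    def test_three_value_summary(self):
        t = table_from_groups({"sp a": [1, 2, 3]})
        row = summarize_characters(t).set_index("character").loc["DP"]
        assert (row["min"], row["max"], row["mean"], row["sd"], row["n"]) == \
            (1, 3, 2.0, 1.0, 3)
        assert row["formatted"] == "1–3; 2 ± 1 (3)"

    def test_single_value_has_undefined_sd(self):
        t = table_from_groups({"sp a": [5]})
        row = summarize_characters(t).set_index("character").loc["DP"]
        assert row["n"] == 1 and np.isnan(row["sd"])
        assert "(1)" in row["formatted"]

    def test_constant_column_has_zero_sd(self):
        t = table_from_groups({"sp a": [15, 15, 15]})
        row = summarize_characters(t).set_index("character").loc["DP"]
        assert row["sd"] == 0.0

    def test_measurements_reported_in_percent_sl(self):
        rows = [{"specimen_id": "x1", "species": "sp a", "SL_mm": 200.0,
                 "HL": 43.4},
                {"specimen_id": "x2", "species": "sp a", "SL_mm": 100.0,
                 "HL": 20.0}]
        t = MorphTable(pd.DataFrame(rows))
        row = summarize_characters(t).set_index("character").loc["HL"]
        assert row["unit"] == "%SL"
        assert row["min"] == pytest.approx(20.0)
        assert row["max"] == pytest.approx(21.7)

    def test_qualitative_states_tallied(self, morph_fixture):
        t, _ = morph_fixture
        summary = summarize_characters(t)
        row = summary[(summary["species"] == "Hyperoplus lanceolatus")
                      & (summary["character"] == "DSSS")].iloc[0]
        assert row["formatted"] == "yes (20)"


class TestVariableSelection:
    def test_constant_and_composite_columns_excluded(self, morph_fixture):
        t, _ = morph_fixture
        selected = select_dfa_variables(t, "meristic")
        assert "CR" not in selected   # invariant count
        assert "GR" not in selected   # composite of UR + LR
        assert "TV" not in selected   # composite of PV + CV
        assert {"DP", "DR", "AR", "PR", "LR", "PV", "CV"} <= set(selected)

    def test_morphometric_mode_returns_measurements(self, morph_fixture):
        t, _ = morph_fixture
        selected = select_dfa_variables(t, "morphometric")
        assert len(selected) == 19

    def test_zero_variance_measurement_dropped(self):
        rows = []
        for sp, hl in (("sp a", 20.0), ("sp b", 25.0)):
            for i in range(3):
                rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                             "SL_mm": 100.0, "HL": hl + i, "SNL": 6.0})
        t = MorphTable(pd.DataFrame(rows))
        assert select_dfa_variables(t, "morphometric") == ["HL"]

    def test_no_varying_columns_rejected(self):
        t = table_from_groups({"sp a": [5, 5], "sp b": [5, 5]})
        with pytest.raises(ValueError, match="variation"):
            select_dfa_variables(t, "meristic")

    def test_unknown_mode_rejected(self, morph_fixture):
        t, _ = morph_fixture
        with pytest.raises(ValueError, match="mode"):
            select_dfa_variables(t, "qualitative")


class TestDiscriminantAnalysis:
    def test_one_dimensional_hand_computed_example(self):
        # groups {0,1} and {10,11}: B = 100, W = 1
        t = table_from_groups({"sp a": [0, 1], "sp b": [10, 11]})
        res = discriminant_analysis(t, ["DP"])
        assert res.eigenvalues[0] == pytest.approx(100.0)
        assert res.wilks_lambda == pytest.approx(1.0 / 101.0)
        assert res.explained_pct[0] == pytest.approx(100.0)
        assert res.n_functions == 1

    def test_identical_group_means_give_no_separation(self):
        t = table_from_groups({"sp a": [1, 2, 3], "sp b": [1, 2, 3]})
        res = discriminant_analysis(t, ["DP"])
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)
        assert res.wilks_lambda == pytest.approx(1.0)

    def test_four_groups_eight_variables_give_three_functions(
            self, morph_fixture):
        t, _ = morph_fixture
        res = discriminant_analysis(t, select_dfa_variables(t, "meristic"))
        assert res.n_functions == 3
        assert res.explained_pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert res.wilks_lambda == pytest.approx(
            np.prod(1.0 / (1.0 + res.eigenvalues)))

    def test_matches_brute_force_oracle_three_groups(self):
        rng = np.random.default_rng(21)
        rows = []
        for gi, sp in enumerate(["sp a", "sp b", "sp c"]):
            centre = np.array([gi * 3.0, -gi * 2.0])
            for i in range(8):
                v = centre + rng.normal(0, 1, 2)
                rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                             "SL_mm": 100.0, "DP": v[0], "DR": v[1]})
        t = MorphTable(pd.DataFrame(rows))
        res = discriminant_analysis(t, ["DP", "DR"])
        X = t.df[["DP", "DR"]].to_numpy(float)
        evals, wilks = brute_force_dfa(X, t.df["species"].tolist())
        np.testing.assert_allclose(res.eigenvalues, evals, atol=1e-8)
        assert res.wilks_lambda == pytest.approx(wilks, abs=1e-8)

    def test_wilks_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(31)
        rows = []
        for gi, sp in enumerate(["sp a", "sp b", "sp c"]):
            for i in range(10):
                rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                             "SL_mm": 100.0,
                             "DP": gi * 2 + rng.normal(),
                             "DR": -gi + rng.normal(),
                             "AR": rng.normal()})
        t = MorphTable(pd.DataFrame(rows))
        res = discriminant_analysis(t, ["DP", "DR", "AR"])
        df = t.df.copy()
        m = MANOVA.from_formula("DP + DR + AR ~ species", data=df)
        wilks = m.mv_test().results["species"]["stat"].loc[
            "Wilks' lambda", "Value"]
        assert res.wilks_lambda == pytest.approx(float(wilks), abs=1e-8)

    def test_eigenvalues_invariant_under_linear_transform(self):
        rng = np.random.default_rng(41)
        base = {}
        for gi, sp in enumerate(["sp a", "sp b", "sp c"]):
            base[sp] = np.column_stack([
                gi * 2 + rng.normal(0, 1, 10),
                -gi * 1.5 + rng.normal(0, 1, 10)])
        A = np.array([[2.0, 1.0], [0.5, -1.0]])  # invertible
        b = np.array([5.0, -3.0])

        def make(tfm):
            rows = []
            for sp, X in base.items():
                Y = X @ A + b if tfm else X
                for i, v in enumerate(Y):
                    rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                                 "SL_mm": 100.0, "DP": v[0], "DR": v[1]})
            return MorphTable(pd.DataFrame(rows))

        r1 = discriminant_analysis(make(False), ["DP", "DR"])
        r2 = discriminant_analysis(make(True), ["DP", "DR"])
        np.testing.assert_allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-8)
        assert r1.wilks_lambda == pytest.approx(r2.wilks_lambda, abs=1e-8)

    def test_positive_eigenvalue_count_bounded_by_rank(self):
        rng = np.random.default_rng(51)
        for g, p in ((2, 5), (3, 4), (4, 2)):
            rows = []
            cols = ["DP", "DR", "AR", "PR", "LR"][:p]
            for gi in range(g):
                for i in range(p + 3):
                    row = {"specimen_id": f"g{gi}_{i}",
                           "species": f"sp {gi}", "SL_mm": 100.0}
                    row.update({c: rng.normal() for c in cols})
                    rows.append(row)
            res = discriminant_analysis(MorphTable(pd.DataFrame(rows)), cols)
            assert np.sum(res.eigenvalues > 1e-9) <= min(g - 1, p)

    def test_box_m_zero_for_identical_covariances(self):
        rng = np.random.default_rng(61)
        X = rng.normal(0, 1, (10, 2))
        rows = []
        for gi, sp in enumerate(["sp a", "sp b"]):
            for i, v in enumerate(X + gi * 5):  # shift: same covariance
                rows.append({"specimen_id": f"{sp}_{i}", "species": sp,
                             "SL_mm": 100.0, "DP": v[0], "DR": v[1]})
        res = discriminant_analysis(MorphTable(pd.DataFrame(rows)),
                                    ["DP", "DR"])
        assert res.boxm_stat == pytest.approx(0.0, abs=1e-9)

    def test_complete_case_deletion_counted(self, morph_fixture):
        t, _ = morph_fixture
        df = t.df.copy()
        df.loc[0, "DP"] = np.nan
        res = discriminant_analysis(MorphTable(df),
                                    ["DP", "DR", "AR"])
        assert res.n_dropped == 1

    def test_loo_reclassification_high_at_reference_parameters(
            self, morph_fixture):
        t, _ = morph_fixture
        rate = loo_classification_rate(t, select_dfa_variables(t, "meristic"))
        assert rate >= 0.90

    def test_group_ellipses_cover_each_group(self, morph_fixture):
        t, _ = morph_fixture
        res = discriminant_analysis(t, select_dfa_variables(t, "meristic"))
        ell = res.group_ellipses()
        assert set(ell) == set(res.groups)
        for e in ell.values():
            assert e["cov"].shape == (2, 2) and e["radius2"] > 0


class TestIdentificationKey:
    @pytest.mark.parametrize("row, expected", [
        ({"PCP": "yes", "VTP": "no", "DP": 130, "BSTC": "yes"},
         "Ammodytes tobianus"),
        ({"PCP": "no", "VTP": "yes", "DSSS": "yes"},
         "Hyperoplus lanceolatus"),
        ({"LR": 24, "PCP": "no"}, "Hyperoplus immaculatus"),
        ({"PCP": "yes", "VTP": "no", "DP": 145, "BSTC": "no", "DR": 60},
         "Ammodytes marinus"),
    ])
    def test_worked_examples(self, row, expected):
        result = identification_key(row)
        assert result.species == expected
        assert result.status == "identified"
        assert 0 < result.confidence <= 1.0

    def test_measurements_converted_to_percent_sl(self):
        # PFL 20 mm on a 200 mm fish = 10 %SL: an Ammodytes value
        result = identification_key(
            {"PCP": "yes", "PFL": 20.0, "SL_mm": 200.0, "BSTC": "yes",
             "DP": 130})
        assert result.genus == "Ammodytes"
        assert result.species == "Ammodytes tobianus"

    def test_all_characters_missing_is_indeterminate(self):
        result = identification_key({"specimen_id": "x", "SL_mm": 100.0})
        assert result.status == "indeterminate"
        assert result.genus is None and result.species is None

    def test_conflicting_genus_evidence_is_indeterminate(self):
        # protrusible premaxillae say Ammodytes, vomerine teeth Hyperoplus
        result = identification_key({"PCP": "yes", "VTP": "yes"})
        assert result.status == "indeterminate"

    def test_unknown_reference_state_not_scored(self):
        # BSTC is not clearly detectable in H. lanceolatus: never evaluated
        cfg = default_key_config()
        assert "BSTC" not in cfg["Hyperoplus lanceolatus"]["characters"]

    def test_evidence_lists_each_scored_character(self):
        result = identification_key(
            {"PCP": "yes", "VTP": "no", "DP": 130, "BSTC": "yes"})
        chars = {e["character"] for e in result.evidence}
        assert {"PCP", "VTP", "DP", "BSTC"} <= chars

    def test_simulated_specimens_identified_correctly(self, morph_fixture):
        t, _ = morph_fixture
        calls = [identification_key(row) for _, row in t.df.iterrows()]
        correct = sum(c.species == sp
                      for c, sp in zip(calls, t.df["species"]))
        assert correct / len(t) >= 0.95


class TestMorphTableValidation:
    def test_composite_consistency_enforced(self):
        rows = [{"specimen_id": "x1", "species": "sp a", "SL_mm": 100.0,
                 "UR": 5, "LR": 20, "GR": 26}]
        with pytest.raises(ValueError, match="GR"):
            MorphTable(pd.DataFrame(rows))

    def test_nonpositive_sl_rejected(self):
        rows = [{"specimen_id": "x1", "species": "sp a", "SL_mm": 0.0}]
        with pytest.raises(ValueError, match="SL_mm"):
            MorphTable(pd.DataFrame(rows))

    def test_duplicate_ids_rejected(self):
        rows = [{"specimen_id": "x1", "species": "a", "SL_mm": 1.0},
                {"specimen_id": "x1", "species": "b", "SL_mm": 1.0}]
        with pytest.raises(ValueError, match="duplicate"):
            MorphTable(pd.DataFrame(rows))
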