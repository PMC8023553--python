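import math

import numpy as np
import pandas as pd
import pytest

from dimerfeat import (
    RESIDUE_SUBSETS, benjamini_hochberg, correct_features, group_tests,
    kyte_doolittle, min_max_scale, propensities, summarize,
)


class TestPropensities:
    def test_worked_example_c_leu_is_two(self):
        # dataset of 4 residues (1 LEU, 3 ALA); class X holds one of each,
        # so f_class(L) = 0.5, f_total(L) = 0.25 and C = 2.0
        labels = ["X", "X", "Y", "Y"]
        resn = ["LEU", "ALA", "ALA", "ALA"]
        prop = propensities(labels, resn)
        c_leu = prop[(prop["class"] == "X") & (prop["residue"] == "L")]["c_factor"].iloc[0]
        assert c_leu == pytest.approx(0.5 / 0.25)

    def test_class_matching_total_distribution_gives_unit_factors(self):
        resn = ["LEU", "ALA", "GLY", "LEU", "ALA", "GLY"]
        prop = propensities(["X"] * 3 + ["Y"] * 3, resn)
        present = prop[prop["f_total"] > 0]
        assert np.allclose(present["c_factor"], 1.0)

    def test_weighted_factor_identity(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        labels = rng.choice(["core", "surface", "interface"], size=500)
        resn = rng.choice(aas, size=500)
        prop = propensities(labels, resn)
        for cls, grp in prop.groupby("class"):
            total = (grp["f_total"] * grp["c_factor"]).dropna().sum()
            assert total == pytest.approx(1.0, abs=1e-12)
            assert grp["f_class"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_absent_residue_gets_missing_factor_not_zero(self):
        prop = propensities(["X", "X"], ["ALA", "GLY"])
        trp = prop[prop["residue"] == "W"]
        assert trp["c_factor"].isna().all()

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            propensities([], [])


class TestCorrection:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({
            "class": ["X", "X", "Y"],
            "resn": ["LEU", "ALA", "ALA"],
            "value": [10.0, 4.0, 6.0],
            "rel_asa": [1.0, 2.0, 3.0],
        })

    def test_multiplies_by_factor(self, table):
        prop = propensities(table["class"], table["resn"])
        out = correct_features(table, prop, ["value", "rel_asa"])
        lookup = {(r["class"], r["residue"]): r["c_factor"] for _, r in prop.iterrows()}
        expected = [v * lookup[(c, a)] for v, c, a in
                    zip(table["value"], table["class"], ["L", "A", "A"])]
        np.testing.assert_allclose(out["value"], expected)

    def test_rel_asa_exempt_by_default(self, table):
        prop = propensities(table["class"], table["resn"])
        out = correct_features(table, prop, ["value", "rel_asa"])
        np.testing.assert_array_equal(out["rel_asa"], table["rel_asa"])

    def test_round_trip_restores_original(self, rng):
        n = 200
        df = pd.DataFrame({
            "class": rng.choice(["core", "surf"], n),
            "resn": rng.choice(["ALA", "LEU", "TRP", "ARG"], n),
            "v": rng.normal(size=n),
        })
        prop = propensities(df["class"], df["resn"])
        corrected = correct_features(df, prop, ["v"])
        from dimerfeat.stats import THREE_TO_ONE
        lookup = {(r["class"], r["residue"]): r["c_factor"] for _, r in prop.iterrows()}
        factors = np.array([lookup[(c, THREE_TO_ONE[a])]
                            for c, a in zip(df["class"], df["resn"])])
        np.testing.assert_allclose(corrected["v"] / factors, df["v"], atol=1e-12)

    def test_missing_factor_passes_through_flagged(self, table):
        prop = propensities(table["class"], table["resn"])
        extra = pd.concat([table, pd.DataFrame([{
            "class": "X", "resn": "TRP", "value": 7.0, "rel_asa": 0.0}])],
            ignore_index=True)
        out = correct_features(extra, prop, ["value"])
        assert out["value"].iloc[-1] == pytest.approx(7.0)
        assert bool(out["correction_missing"].iloc[-1])


class TestSummarize:
    def test_quartiles_by_linear_interpolation(self):
        df = pd.DataFrame({"class": ["X"] * 4, "resn": ["ALA"] * 4,
                           "v": [1.0, 2.0, 3.0, 4.0]})
        out = summarize(df, ["class", "resn"], ["v"])
        row = out.iloc[0]
        assert row["q2"] == pytest.approx(2.5)
        assert row["avg"] == pytest.approx(2.5)
        assert row["q1"] == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(3.25)
        assert row["std"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_single_value_degenerate(self):
        df = pd.DataFrame({"class": ["X"], "resn": ["GLY"], "v": [5.0]})
        row = summarize(df, ["class", "resn"], ["v"]).iloc[0]
        assert row["q1"] == row["q2"] == row["q3"] == row["avg"] == 5.0
        assert math.isnan(row["std"])

    def test_rows_ordered_by_increasing_hydropathy(self):
        # Kyte-Doolittle: ARG (-4.5) is the most hydrophilic, ILE (+4.5)
        # the most hydrophobic, so ARG comes first in ascending order
        df = pd.DataFrame({"class": ["X"] * 4,
                           "resn": ["ILE", "ARG", "GLY", "ILE"],
                           "v": [1.0, 2.0, 3.0, 4.0]})
        out = summarize(df, ["class", "resn"], ["v"])
        order = out["resn"].tolist()
        assert order.index("ARG") < order.index("GLY") < order.index("ILE")

    def test_permutation_invariance(self, rng):
        df = pd.DataFrame({"class": rng.choice(["X", "Y"], 100),
                           "resn": rng.choice(["ALA", "LEU"], 100),
                           "v": rng.normal(size=100)})
        out1 = summarize(df, ["class", "resn"], ["v"])
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        out2 = summarize(shuffled, ["class", "resn"], ["v"])
        merged = out1.merge(out2, on=["class", "resn", "feature"], suffixes=("_1", "_2"))
        assert len(merged) == len(out1)
        for col in ("q1", "q2", "q3", "avg", "std", "n"):
            np.testing.assert_allclose(merged[f"{col}_1"], merged[f"{col}_2"])


class TestGroupTests:
    def test_identical_samples_give_t_zero_p_one(self):
        df = pd.DataFrame({"class": ["X"] * 5 + ["Y"] * 5,
                           "v": [1.0, 2, 3, 4, 5] * 2})
        out = group_tests(df, ["v"])
        t_row = out[out["test"] == "t"].iloc[0]
        assert t_row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert t_row["p_value"] == pytest.approx(1.0)

    def test_separated_gaussians_give_tiny_p(self, rng):
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(5.0, 1.0, 100)
        df = pd.DataFrame({"class": ["X"] * 100 + ["Y"] * 100,
                           "v": np.concatenate([a, b])})
        out = group_tests(df, ["v"])
        t_row = out[out["test"] == "t"].iloc[0]
        assert t_row["p_value"] < 1e-10
        # independent classic-formula evaluation of the t statistic
        sp = math.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                       / (len(a) + len(b) - 2))
        t_manual = (a.mean() - b.mean()) / (sp * math.sqrt(1 / len(a) + 1 / len(b)))
        assert t_row["statistic"] == pytest.approx(t_manual, rel=1e-12)

    def test_single_class_raises(self):
        df = pd.DataFrame({"class": ["X"] * 4, "v": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            group_tests(df, ["v"])

    def test_insufficient_n_yields_missing_p_with_reason(self):
        df = pd.DataFrame({"class": ["X", "Y", "Y", "Y"], "v": [1.0, 2, 3, 4]})
        out = group_tests(df, ["v"])
        t_row = out[out["test"] == "t"].iloc[0]
        assert math.isnan(t_row["p_value"]) and t_row["note"] == "insufficient n"

    def test_anova_present_for_three_classes(self, rng):
        df = pd.DataFrame({"class": rng.choice(["A", "B", "C"], 90),
                           "v": rng.normal(size=90)})
        out = group_tests(df, ["v"])
        assert (out["test"] == "t").sum() == 3
        assert (out["test"] == "anova").sum() == 1


def test_residue_subsets_are_exactly_as_defined():
    assert RESIDUE_SUBSETS["charged"] == frozenset("DEKR")
    assert RESIDUE_SUBSETS["gas"] == frozenset("GAS")
    assert RESIDUE_SUBSETS["non_polar"] == frozenset("AVILMFW")
    assert RESIDUE_SUBSETS["excluded"] == frozenset("CGP")


def test_kyte_doolittle_scale_signs():
    kd = kyte_doolittle()
    assert len(kd) == 20
    assert kd["I"] > 0 > kd["R"]
    assert kd["I"] == pytest.approx(4.5) and kd["R"] == pytest.approx(-4.5)


def test_benjamini_hochberg_monotone_and_bounded(rng):
    p = rng.uniform(size=50)
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-12).all() and (q <= 1.0).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_min_max_scale_range():
    v = np.array([3.0, 5.0, 9.0])
    out = min_max_scale(v)
    assert out.min() == 0.0 and out.max() == 1.0
    assert (min_max_scale(np.ones(4)) == 0).all()
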