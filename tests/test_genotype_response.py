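"""Genotype-panel statistics: Dunnett, proportional effects, stage
profiles, standardization, Tukey CLD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microroot import genotype_response as gr
from microroot import synthetic_data as sd

from conftest import make_condition_table


class TestDunnett:
    def test_treatment_identical_to_control_is_null(self, rng):
        vals = rng.normal(5, 1, 8)
        table = make_condition_table({"NB": vals, "S1": vals.copy()})
        res = gr.dunnett_vs_control(table, n_mc=5000, seed=0)
        assert res["diff"].iloc[0] == pytest.approx(0.0)
        assert res["p_adjusted"].iloc[0] > 0.9

    def test_single_treatment_reduces_to_pooled_t(self, rng):
        x = rng.normal(5.8, 1, 10)
        c = rng.normal(5, 1, 10)
        table = make_condition_table({"NB": c, "S1": x})
        res = gr.dunnett_vs_control(table, n_mc=200_000, seed=3)
        t_p = stats.ttest_ind(x, c, equal_var=True).pvalue
        mc_se = 2 * np.sqrt(t_p * (1 - t_p) / 200_000)
        assert abs(res["p_adjusted"].iloc[0] - t_p) < max(2 * mc_se, 1e-3)

    def test_adjusted_p_at_least_unadjusted_and_grows_with_family(self, rng):
        arms = {"NB": rng.normal(0, 1, 6)}
        for i in range(6):
            arms[f"S{i + 1}"] = rng.normal(0.8, 1, 6)
        small = gr.dunnett_vs_control(
            make_condition_table({k: arms[k] for k in ["NB", "S1", "S2"]}),
            n_mc=50_000, seed=1)
        large = gr.dunnett_vs_control(make_condition_table(arms),
                                      n_mc=50_000, seed=1)
        assert (small["p_adjusted"] >= small["p_unadjusted"] - 1e-12).all()
        # the same contrast pays a larger multiplicity penalty in the
        # bigger family (up to MC noise)
        p_small = small.set_index("treatment")["p_adjusted"]["S1"]
        p_large = large.set_index("treatment")["p_adjusted"]["S1"]
        assert p_large >= p_small - 0.01

    def test_matches_scipy_multivariate_t_dunnett(self, rng):
        arms = {"NB": rng.normal(0, 1, 8),
                "S1": rng.normal(1.0, 1, 8),
                "S2": rng.normal(0.2, 1, 8),
                "S3": rng.normal(-0.7, 1, 8)}
        res = gr.dunnett_vs_control(make_condition_table(arms),
                                    n_mc=200_000, seed=2)
        ref = stats.dunnett(arms["S1"], arms["S2"], arms["S3"],
                            control=arms["NB"])
        got = res.set_index("treatment")["p_adjusted"]
        for name, expected in zip(["S1", "S2", "S3"], ref.pvalue):
            assert got[name] == pytest.approx(expected, abs=5e-3)

    def test_all_values_equal_gives_p_one(self):
        table = make_condition_table({"NB": [2.0] * 4, "S1": [2.0] * 4})
        res = gr.dunnett_vs_control(table, n_mc=1000, seed=0)
        assert res["p_adjusted"].iloc[0] == 1.0

    def test_single_arm_input_rejected(self, rng):
        with pytest.raises(ValueError):
            gr.dunnett_vs_control(make_condition_table(
                {"NB": rng.normal(size=5)}))


class TestProportionalEffect:
    def test_identical_arms_classified_no_change(self, rng):
        v = rng.normal(10, 1, 10)
        table = make_condition_table({"NB": v, "NB+NPA": v.copy(),
                                      "S1": v, "S1+NPA": v.copy()})
        res = gr.proportional_molecule_effect(table, "Col-0", "NPA")
        assert (res["proportion"] == 0).all()
        assert (res["class"] == "no_change").all()

    def test_halving_means_gives_minus_half(self):
        table = make_condition_table({
            "S1": np.array([10.0] * 6) + np.linspace(-0.1, 0.1, 6),
            "S1+Kyn": np.array([5.0] * 6) + np.linspace(-0.1, 0.1, 6),
            "NB": np.full(6, 10.0)})
        res = gr.proportional_molecule_effect(table, "Col-0", "Kyn")
        row = res.set_index("treatment").loc["S1"]
        assert row["proportion"] == pytest.approx(-0.5, abs=1e-9)
        assert row["class"] == "decrease"

    def test_planted_halving_recovered_over_seeds(self):
        props = []
        for seed in range(20):
            g = np.random.default_rng(seed)
            table = make_condition_table({
                "NB": g.normal(10, 1, 10),
                "S1": g.normal(10, 1, 10),
                "S1+Kyn": g.normal(5, 1, 10)})
            res = gr.proportional_molecule_effect(table, "Col-0", "Kyn")
            props.append(res["proportion"].iloc[0])
        assert abs(np.mean(props) + 0.5) < 0.1

    def test_unmatched_arm_skipped_with_warning(self, rng):
        table = make_condition_table({"NB": rng.normal(10, 1, 5),
                                      "S1": rng.normal(10, 1, 5),
                                      "S1+NPA": rng.normal(9, 1, 5),
                                      "S2": rng.normal(10, 1, 5)})
        with pytest.warns(UserWarning, match="S2"):
            res = gr.proportional_molecule_effect(table, "Col-0", "NPA")
        assert list(res["treatment"]) == ["S1"]


class TestStandardize:
    def test_two_treatments_give_plus_minus_707(self):
        eff = pd.DataFrame({"genotype": ["g", "g"],
                            "treatment": ["a", "b"], "effect": [1.0, 3.0]})
        out = gr.standardize_within_genotype(eff)
        assert sorted(out["z"].round(3)) == [-0.707, 0.707]

    def test_all_equal_effects_raise(self):
        eff = pd.DataFrame({"genotype": "g", "treatment": list("abc"),
                            "effect": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="zero SD"):
            gr.standardize_within_genotype(eff)

    def test_output_has_mean_zero_sd_one_per_genotype(self, rng):
        eff = pd.DataFrame({
            "genotype": np.repeat(["g1", "g2"], 8),
            "treatment": list("abcdefgh") * 2,
            "effect": rng.normal(size=16)})
        out = gr.standardize_within_genotype(eff)
        for _, sub in out.groupby("genotype"):
            assert sub["z"].mean() == pytest.approx(0.0, abs=1e-12)
            assert sub["z"].std(ddof=1) == pytest.approx(1.0)


class TestStageProfiles:
    def test_proportions_from_counts(self):
        rows = []
        for stage, n in [("I", 2), ("II", 2), ("E", 4)]:
            rows.append(("Col-0", "S1", "R1", "p1", stage, float(n)))
        for stage in ("I", "II", "E"):
            rows.append(("Col-0", "NB", "R1", "p1", stage, 1.0))
            rows.append(("Col-0", "NB", "R1", "p2", stage, 1.0))
        rows.append(("Col-0", "S1", "R1", "p2", "I", 0.0))
        table = pd.DataFrame(rows, columns=["genotype", "treatment",
                                            "replicate", "plant_id",
                                            "stage", "response"])
        profile, _ = gr.primordia_stage_profile(table, n_mc=100, seed=0)
        row = profile.set_index("treatment").loc["S1"]
        assert row["I"] == pytest.approx(0.25)
        assert row["II"] == pytest.approx(0.25)
        assert row["E"] == pytest.approx(0.5)
        assert row["total"] == 8
        non_total = profile.set_index("treatment")[["I", "II", "E"]].sum(axis=1)
        assert np.allclose(non_total, 1.0, atol=1e-12)

    def test_all_zero_treatment_flagged(self):
        rows = [("Col-0", t, "R1", f"p{i}", s, c)
                for t, c in [("NB", 1.0), ("S1", 0.0)]
                for s in ("I", "E") for i in range(3)]
        table = pd.DataFrame(rows, columns=["genotype", "treatment",
                                            "replicate", "plant_id",
                                            "stage", "response"])
        profile, _ = gr.primordia_stage_profile(table, n_mc=100, seed=0)
        row = profile.set_index("treatment").loc["S1"]
        assert bool(row["empty"])
        assert row[["I", "E"]].sum() == 0.0

    def test_unknown_stage_and_negative_counts_rejected(self):
        bad = pd.DataFrame({"genotype": ["g"], "treatment": ["NB"],
                            "replicate": ["R1"], "plant_id": ["p1"],
                            "stage": ["VIII"], "response": [1.0]})
        with pytest.raises(ValueError, match="stage"):
            gr.primordia_stage_profile(bad)
        bad2 = bad.assign(stage="I", response=-1.0)
        with pytest.raises(ValueError, match="negative"):
            gr.primordia_stage_profile(bad2)

    def test_planted_early_stage_doubling_detected_in_totals(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            table, truth = sd.simulate_primordia(n_strains=4, n_plants=10,
                                                 seed=seed)
            if not truth.active_strains:
                n_seeds -= 1
                continue
            _, dun = gr.primordia_stage_profile(table, n_mc=10_000,
                                                seed=seed)
            sig = set(dun.loc[dun["significant"], "treatment"])
            hits += len(sig & truth.active_strains) / len(truth.active_strains)
        assert hits / n_seeds >= 0.8


class TestStageCorrelation:
    def test_proportional_stage_counts_give_r_one(self):
        sc = pd.DataFrame({"I": [1.0, 2, 3, 4, 5]},
                          index=[f"S{i}" for i in range(5)])
        emerged = pd.Series([2.0, 4, 6, 8, 10], index=sc.index)
        out = gr.stage_phenotype_correlation(sc, emerged)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_planted_coupling_found_only_in_early_stages(self):
        found, spurious = [], []
        for seed in range(25):
            table, truth = sd.simulate_primordia(
                n_strains=12, n_plants=10, seed=seed)
            sc = table.pivot_table(index="treatment", columns="stage",
                                   values="response", aggfunc="sum")
            out = gr.stage_phenotype_correlation(sc.drop(columns="E"),
                                                 sc["E"])
            sig = set(out.loc[out["significant"].fillna(False), "stage"])
            found.append(len(sig & {"I", "II", "III"}) / 3)
            spurious.append(len(sig - {"I", "II", "III"}) / 4)
        assert np.mean(found) >= 0.8
        assert np.mean(spurious) < 0.3

    def test_shuffled_emergence_rejection_rate_controlled(self):
        gen = np.random.default_rng(42)
        n_tests, n_rej = 0, 0
        for _ in range(200):
            sc = pd.DataFrame(gen.poisson(20, size=(12, 3)),
                              columns=["I", "II", "III"],
                              index=[f"S{i}" for i in range(12)])
            emerged = pd.Series(gen.poisson(20, 12), index=sc.index)
            out = gr.stage_phenotype_correlation(sc, emerged)
            n_tests += out["q"].notna().sum()
            n_rej += int((out["q"] < 0.05).sum())
        assert n_rej / n_tests <= 0.07

    def test_constant_stage_vector_reported_missing(self):
        sc = pd.DataFrame({"I": [2.0, 2, 2, 2], "II": [1.0, 2, 3, 4]},
                          index=list("abcd"))
        emerged = pd.Series([1.0, 2, 3, 4], index=sc.index)
        out = gr.stage_phenotype_correlation(sc, emerged)
        assert np.isnan(out.set_index("stage").loc["I", "r"])


class TestTukeyCLD:
    def test_identical_groups_share_a_letter(self, rng):
        v = rng.normal(5, 1, 10)
        table = make_condition_table({"g1": v, "g2": v.copy()})
        out = gr.tukey_cld(table)
        assert set(out["letters"]) == {"a"}

    def test_separated_groups_get_distinct_letters(self, rng):
        table = make_condition_table({
            "g0": rng.normal(0, 0.1, 10),
            "g1": rng.normal(10, 0.1, 10),
            "g2": rng.normal(20, 0.1, 10)})
        out = gr.tukey_cld(table)
        letters = out.set_index("treatment")["letters"]
        assert len({letters["g0"], letters["g1"], letters["g2"]}) == 3
        assert all(len(l) == 1 for l in letters)

    def test_letters_invariant_to_input_order(self, rng):
        arms = {f"g{i}": rng.normal(i * 0.8, 1, 8) for i in range(4)}
        t1 = make_condition_table(arms)
        t2 = make_condition_table(dict(reversed(list(arms.items()))))
        out1 = gr.tukey_cld(t1).set_index("treatment")["letters"]
        out2 = gr.tukey_cld(t2).set_index("treatment")["letters"]
        pd.testing.assert_series_equal(out1, out2)

    def test_shared_letter_iff_tukey_not_significant(self, rng):
        arms = {f"g{i}": rng.normal([0, 0.5, 3, 3.2][i], 1, 10)
                for i in range(4)}
        out = gr.tukey_cld(make_condition_table(arms), alpha=0.05)
        letters = out.set_index("treatment")["letters"]
        names = sorted(arms)
        ref = stats.tukey_hsd(*[arms[g] for g in names])
        for i, gi in enumerate(names):
            for j, gj in enumerate(names):
                if i >= j:
                    continue
                share = bool(set(letters[gi]) & set(letters[gj]))
                assert share == (ref.pvalue[i, j] >= 0.05)
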