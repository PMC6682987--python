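"""Statistical reporting: ANOVA, effect sizes, ratios, regressions."""

import numpy as np
import pandas as pd
import pytest

from dietscore import reference
from dietscore.report import (
    anova_oneway,
    bonferroni,
    country_summary,
    format_p,
    partial_eta_squared,
    pearson_r,
    q5_q1_ratio,
    quintile_summary,
    regress_scores,
    score_strata_report,
)


class TestAnova:
    def test_hand_computed_two_groups(self):
        eff = anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert eff.ss_between == pytest.approx(13.5)
        assert eff.ss_within == pytest.approx(4.0)
        assert eff.eta_sq_p == pytest.approx(13.5 / 17.5)

    def test_identical_means_zero_effect(self):
        eff = anova_oneway([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert eff.eta_sq_p == pytest.approx(0.0)
        assert eff.p_value == pytest.approx(1.0, abs=1e-9)

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=300)
        y = (y - y.mean()) / y.std()
        labels = rng.choice(list("abcd"), 300)
        eff = anova_oneway(y, labels)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert abs(eff.ss_between + eff.ss_within - ss_total) < 1e-9

    def test_eta_squared_affine_invariant(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=120)
        labels = rng.choice(list("abc"), 120)
        e1 = anova_oneway(y, labels).eta_sq_p
        e2 = anova_oneway(7.3 * y - 150.0, labels).eta_sq_p
        assert e1 == pytest.approx(e2, rel=1e-10)

    def test_pairwise_bonferroni_count_and_ordering(self):
        rng = np.random.default_rng(7)
        y = np.concatenate([rng.normal(m, 1, 30) for m in (0, 0.2, 5)])
        labels = np.repeat(list("abc"), 30)
        eff = anova_oneway(y, labels)
        assert len(eff.pairwise) == 3
        assert (eff.pairwise["p_bonferroni"] >= eff.pairwise["p_raw"]).all()
        assert (eff.pairwise["p_bonferroni"] <= 1.0).all()

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1, 2, 3], ["a", "a", "a"])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01], 5) == [0.05]
        assert bonferroni([0.30], 5) == [1.0]
        assert bonferroni([0.0], 99) == [0.0]

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)


def test_partial_eta_squared_definition():
    assert partial_eta_squared(10.0, 30.0) == pytest.approx(0.25)
    assert partial_eta_squared(0.0, 5.0) == 0.0


class TestQ5Q1Ratio:
    def test_published_worked_examples(self):
        q1, q5 = reference.QUINTILE_Q1_Q5_MEANS["nuts_seeds"]
        assert q5_q1_ratio(q1, q5) == 197.20
        q1, q5 = reference.QUINTILE_Q1_Q5_MEANS["processed_meats"]
        assert q5_q1_ratio(q1, q5) == 7.24
        q1, q5 = reference.QUINTILE_Q1_Q5_MEANS["polyunsaturated_fat_pct"]
        assert q5_q1_ratio(q1, q5) == 1.92

    def test_equal_means_give_one(self):
        assert q5_q1_ratio(4.2, 4.2) == 1.00

    def test_zero_first_quintile_is_undefined_not_infinite(self):
        assert q5_q1_ratio(0.0, 5.0) is None


class TestQuintileSummary:
    def test_pooled_means_conserve_overall_mean(self, medium_scores):
        summary = quintile_summary(medium_scores["usual"], medium_scores["quintiles"])
        for _, row in summary.iterrows():
            ns = np.array([row[f"q{q}_n"] for q in range(1, 6)])
            means = np.array([row[f"q{q}_mean"] for q in range(1, 6)])
            pooled = (ns * means).sum() / ns.sum()
            assert pooled == pytest.approx(
                medium_scores["usual"][row["factor"]].mean(), rel=1e-9
            )

    def test_sorted_by_descending_ratio_within_direction(self, medium_scores):
        summary = quintile_summary(medium_scores["usual"], medium_scores["quintiles"])
        for _, block in summary.groupby("direction"):
            ratios = block["ratio_q5_q1"].to_numpy(dtype=float)
            assert (np.diff(ratios) <= 1e-12).all()

    def test_quintile_sizes_near_equal(self, medium_scores):
        summary = quintile_summary(medium_scores["usual"], medium_scores["quintiles"])
        ns = summary[[f"q{q}_n" for q in range(1, 6)]].to_numpy()
        assert (ns.sum(axis=1) == len(medium_scores["usual"])).all()


class TestStrataReport:
    def test_strata_rows_and_effects(self, medium_scores):
        from dietscore.anthro import classify_subjects

        anthro = classify_subjects(medium_scores["subjects"])
        strata, effects, pairwise = score_strata_report(
            medium_scores["dqs"], medium_scores["dds"],
            medium_scores["subjects"], anthro,
        )
        total = strata[strata["stratifier"] == "total"].iloc[0]
        assert total["n"] == len(medium_scores["subjects"])
        sex_rows = strata[strata["stratifier"] == "sex"]
        assert set(sex_rows["level"]) == {"male", "female"}
        assert sex_rows["n"].sum() == total["n"]
        sel = strata[strata["stratifier"] == "sel"].set_index("level")
        assert (
            sel.loc["high", "healthy_std_mean"]
            > sel.loc["middle", "healthy_std_mean"]
            > sel.loc["low", "healthy_std_mean"]
        )
        assert ((effects["eta_sq_p"] >= 0) & (effects["eta_sq_p"] <= 1)).all()
        assert (pairwise["p_bonferroni"] >= pairwise["p_raw"]).all()

    def test_single_country_has_no_country_posthoc(self, medium_scores):
        from dietscore.anthro import classify_subjects

        subjects = medium_scores["subjects"]
        peru = subjects[subjects["country"] == "Peru"]
        ids = set(peru["subject_id"])
        dqs = medium_scores["dqs"][medium_scores["dqs"]["subject_id"].isin(ids)]
        dds = medium_scores["dds"][medium_scores["dds"]["subject_id"].isin(ids)]
        strata, effects, pairwise = score_strata_report(
            dqs, dds, peru, classify_subjects(peru)
        )
        country_rows = strata[(strata["stratifier"] == "country") & (strata["n"] > 0)]
        assert len(country_rows) == 1
        assert not (effects["stratifier"] == "country").any()


class TestRegressions:
    def test_outcome_equal_to_predictor(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [1.0, 2.0, 3.0, 4.0]})
        (fit,) = regress_scores(df, "y", ("x",))
        assert fit.r == pytest.approx(1.0) and fit.r_squared == pytest.approx(1.0)

    def test_total_raw_is_exact_sum_of_components(self, medium_scores):
        (fit,) = regress_scores(
            medium_scores["dqs"], "total_raw", ("healthy_raw", "unhealthy_raw")
        )
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients["healthy_raw"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["unhealthy_raw"] == pytest.approx(1.0, abs=1e-8)

    def test_independent_outcome_near_zero_r2(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"y": rng.normal(size=5000), "x": rng.normal(size=5000)})
        (fit,) = regress_scores(df, "y", ("x",))
        assert fit.r_squared < 0.01

    def test_collinear_predictors_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        df = pd.DataFrame({"y": rng.normal(size=50), "a": x, "b": 2 * x})
        (fit,) = regress_scores(df, "y", ("a", "b"))
        assert fit.collinear and fit.coefficients == {}

    def test_stratified_fit_covers_all_levels(self, medium_scores):
        df = medium_scores["dqs"].merge(
            medium_scores["subjects"][["subject_id", "sex"]], on="subject_id"
        ).merge(medium_scores["dds"][["subject_id", "dds"]], on="subject_id")
        fits = regress_scores(df, "dds", ("healthy_std",), strata="sex")
        assert [f.stratum for f in fits] == ["all", "female", "male"]


def test_pearson_r_identity_and_symmetry():
    rng = np.random.default_rng(10)
    x, y = rng.normal(size=100), rng.normal(size=100)
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, y)[0] == pytest.approx(pearson_r(y, x)[0])


def test_p_value_display_convention():
    assert format_p(0.03124) == "0.0312"
    assert format_p(5e-5) == "<0.0001"


def test_country_summary_matches_groupby(medium_scores):
    t2 = country_summary(medium_scores["usual"], medium_scores["subjects"])
    df = medium_scores["usual"].merge(
        medium_scores["subjects"][["subject_id", "country"]], on="subject_id"
    )
    row = t2[t2["factor"] == "fish"].iloc[0]
    assert row["Peru_mean"] == pytest.approx(
        df.loc[df["country"] == "Peru", "fish"].mean()
    )
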