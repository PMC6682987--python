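"""Usual-intake estimation: energy adjustment, shrinkage algebra, recovery."""

import numpy as np
import pandas as pd
import pytest

from dietscore.core import DEFAULT_FACTORS, ValidationError
from dietscore.usual import (
    UsualIntakeOptions,
    adjust_to_2000kcal,
    build_usual_table,
    estimate_usual,
)

from conftest import two_day_subgroup

RAW = UsualIntakeOptions(transform="none")


class TestEnergyAdjustment:
    @pytest.mark.parametrize(
        "amount,energy,expected",
        [(10.0, 2000.0, 10.0), (10.0, 4000.0, 5.0), (33.2, 1800.0, 33.2 * 2000 / 1800)],
    )
    def test_linear_scaling(self, amount, energy, expected):
        assert adjust_to_2000kcal(amount, energy) == pytest.approx(expected)

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            adjust_to_2000kcal(10.0, 0.0)

    def test_percent_energy_factor_rejected(self):
        with pytest.raises(ValueError, match="energy-adjusted"):
            adjust_to_2000kcal(10.0, 2000.0, unit="%energy")


def days_frame(values_by_subject):
    rows = [
        {"subject_id": sid, "value": v}
        for sid, vals in values_by_subject.items()
        for v in vals
    ]
    return pd.DataFrame(rows)


class TestShrinkageEdgeCases:
    def test_no_within_variance_returns_subject_means(self):
        df = days_frame({"A": [10, 10], "B": [30, 30], "C": [20, 20]})
        usual, fit = estimate_usual(df)
        assert fit.sigma2_w == 0.0
        assert usual.to_dict() == pytest.approx({"A": 10.0, "B": 30.0, "C": 20.0})

    def test_no_between_variance_returns_subgroup_mean(self):
        # all subjects share one latent value; day noise is pure within-person
        df = days_frame({"A": [18, 22], "B": [22, 18], "C": [19, 21], "D": [21, 19]})
        usual, fit = estimate_usual(df, options=RAW)
        assert fit.sigma2_b == 0.0
        assert np.allclose(usual.to_numpy(), 20.0)

    def test_all_identical_returns_constant(self):
        df = days_frame({"A": [5, 5], "B": [5, 5]})
        usual, _ = estimate_usual(df)
        assert np.allclose(usual.to_numpy(), 5.0)

    def test_all_zero_cell_returns_zero(self):
        df = days_frame({"A": [0, 0], "B": [0, 0]})
        usual, _ = estimate_usual(df)
        assert np.allclose(usual.to_numpy(), 0.0)

    def test_single_subject_falls_back_to_day_mean(self):
        df = days_frame({"A": [10, 30]})
        usual, fit = estimate_usual(df)
        assert fit.fallback
        assert usual["A"] == pytest.approx(20.0)

    def test_no_two_day_subject_falls_back_with_flag(self):
        df = days_frame({"A": [10], "B": [30], "C": [14]})
        usual, fit = estimate_usual(df)
        assert fit.fallback
        assert usual.to_dict() == pytest.approx({"A": 10.0, "B": 30.0, "C": 14.0})

    def test_no_shrink_returns_day_means(self):
        df = days_frame({"A": [10, 30], "B": [5, 15], "C": [1, 3]})
        usual, _ = estimate_usual(df, options=UsualIntakeOptions(shrink=False))
        assert usual.to_dict() == pytest.approx({"A": 20.0, "B": 10.0, "C": 2.0})


class TestShrinkageProperties:
    def test_mean_preserved_on_estimation_scale(self):
        days, _ = two_day_subgroup(200, seed=3)
        usual, _ = estimate_usual(days, options=RAW)
        raw_means = days.groupby("subject_id")["value"].mean()
        assert usual.mean() == pytest.approx(raw_means.mean(), rel=1e-12)

    def test_variance_never_exceeds_raw_means(self):
        for seed in range(5):
            days, _ = two_day_subgroup(150, seed=seed)
            raw_means = days.groupby("subject_id")["value"].mean()
            for opts in (RAW, UsualIntakeOptions()):
                usual, _ = estimate_usual(days, options=opts)
                assert usual.var() <= raw_means.var() * (1 + 1e-12)

    def test_lambda_within_unit_interval(self, medium_scores):
        lam = medium_scores["usual_meta"]["lambda_2day"].dropna()
        assert ((lam >= 0) & (lam <= 1)).all()

    def test_monotone_in_own_day_values(self):
        days, _ = two_day_subgroup(60, seed=8)
        target = days["subject_id"].iloc[0]
        for opts in (RAW, UsualIntakeOptions()):
            base, _ = estimate_usual(days, options=opts)
            bumped = days.copy()
            sel = bumped["subject_id"] == target
            bumped.loc[sel, "value"] += 10.0
            after, _ = estimate_usual(bumped, options=opts)
            assert after[target] >= base[target]

    def test_estimator_beats_raw_means_on_correlation_with_truth(self):
        """Shrinkage recovers latent usual intake better than 2-day means."""
        gains = []
        for seed in range(10):
            days, latent = two_day_subgroup(500, seed=seed)
            est, _ = estimate_usual(days)
            raw = days.groupby("subject_id")["value"].mean()
            gains.append(
                np.corrcoef(est.to_numpy(), latent)[0, 1]
                - np.corrcoef(raw.to_numpy(), latent)[0, 1]
            )
        assert np.mean(gains) > 0

    def test_variance_components_recovered_at_n2000(self):
        """Raw-scale components match the generator's closed-form truth."""
        b_est, w_est = [], []
        for seed in (7, 123, 2024):
            days, _ = two_day_subgroup(2000, seed=seed)
            _, fit = estimate_usual(days, options=RAW)
            b_est.append(fit.sigma2_b)
            w_est.append(fit.sigma2_w)
        # latent ~ lognormal(mean 50, sd 20): Var = 400; within-person
        # variance = E[latent^2] * CV^2 = (50^2 + 20^2) * 0.09 = 261
        assert np.mean(b_est) == pytest.approx(400.0, rel=0.10)
        assert np.mean(w_est) == pytest.approx(261.0, rel=0.15)

    def test_log_scale_components_close_to_theory(self):
        # log-scale truth: sigma2_b = log1p((20/50)^2), sigma2_w = log1p(0.09);
        # the +c offset attenuates both slightly, hence the loose bound
        days, _ = two_day_subgroup(2000, seed=123)
        _, fit = estimate_usual(days)
        assert fit.sigma2_b == pytest.approx(np.log1p(0.16), rel=0.20)
        assert fit.sigma2_w == pytest.approx(np.log1p(0.09), rel=0.20)


class TestTwoPartMode:
    def test_two_part_scales_by_consumption_probability(self):
        rng = np.random.default_rng(4)
        n = 400
        latent = rng.lognormal(np.log(20), 0.4, n)
        p = 0.6
        days = np.repeat(latent, 2) * rng.lognormal(-0.02, 0.2, 2 * n)
        consumed = rng.random(2 * n) < p
        days = np.where(consumed, days / p, 0.0)
        df = pd.DataFrame(
            {"subject_id": np.repeat([f"S{i:04d}" for i in range(n)], 2), "value": days}
        )
        fish = next(f for f in DEFAULT_FACTORS if f.name == "fish")
        usual, _ = estimate_usual(df, fish, UsualIntakeOptions(two_part=True))
        assert usual.mean() == pytest.approx(latent.mean(), rel=0.15)
        assert (usual >= 0).all()


class TestBuildUsualTable:
    def test_adjustment_applied_before_estimation(self):
        """Two 4000-kcal days with 20 g fish each -> usual 10 g/d."""
        from dietscore.synthetic import GeneratorSpec, generate_population

        subjects, recalls, _ = generate_population(GeneratorSpec(subjects_per_cell=2, seed=0))
        recalls = recalls.copy()
        recalls["energy_kcal"] = 4000.0
        recalls["fish"] = 20.0
        usual, _ = build_usual_table(subjects, recalls)
        assert np.allclose(usual["fish"], 10.0)

    def test_percent_energy_passes_through_unadjusted(self):
        from dietscore.synthetic import GeneratorSpec, generate_population

        subjects, recalls, _ = generate_population(GeneratorSpec(subjects_per_cell=2, seed=0))
        recalls = recalls.copy()
        recalls["energy_kcal"] = 4000.0
        recalls["saturated_fat_pct"] = 8.0
        usual, _ = build_usual_table(subjects, recalls)
        assert np.allclose(usual["saturated_fat_pct"], 8.0)

    def test_table_covers_all_subjects_and_factors(self, medium_scores):
        usual = medium_scores["usual"]
        subjects = medium_scores["subjects"]
        assert len(usual) == len(subjects)
        assert set(f.name for f in DEFAULT_FACTORS) <= set(usual.columns)
        assert not usual.isna().any().any()
        assert (usual[[f.name for f in DEFAULT_FACTORS]] >= 0).all().all()

    def test_subject_without_recalls_rejected(self, medium_population):
        subjects, recalls, _ = medium_population
        with pytest.raises(ValidationError, match="zero recall days"):
            build_usual_table(subjects, recalls[recalls["subject_id"] != "S000001"])
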