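"""Statistical reporting: quintile summaries, ANOVA with partial eta-squared,
Bonferroni post-hoc comparisons, stratified score tables, and regressions.

The reporting layer mirrors a survey-style results section: per-factor
quintile means with fifth-to-first-quintile ratios, per-country usual-intake
means, score means stratified by demographics and anthropometry with one-way
ANOVA per stratifier (effect size as partial eta-squared,
SS_effect / (SS_effect + SS_error)), Bonferroni-adjusted pairwise t tests,
and ordinary least-squares regressions reporting the multiple correlation R
and R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core import (
    AGE_GROUPS,
    COUNTRIES,
    DEFAULT_FACTORS,
    FactorDef,
    SELS,
    SEXES,
    round_half_up,
)
from .anthro import BMI_CLASSES


def bonferroni(pvals, m: int) -> list[float]:
    """Bonferroni adjustment: p -> min(1, m * p)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    out = []
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0,1]: {p}")
        out.append(min(1.0, m * p))
    return out


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be nonnegative")
    total = ss_effect + ss_error
    return ss_effect / total if total > 0 else 0.0


@dataclass
class EffectSummary:
    """One-way ANOVA of an outcome over a grouping factor."""

    outcome: str
    grouping: str
    f_stat: float
    p_value: float
    eta_sq_p: float
    ss_between: float
    ss_within: float
    group_stats: pd.DataFrame  # level, n, mean, sd
    pairwise: pd.DataFrame  # level_a, level_b, p_raw, p_bonferroni


def anova_oneway(
    values, labels, outcome: str = "outcome", grouping: str = "group"
) -> EffectSummary:
    """One-way fixed-effects decomposition with Bonferroni pairwise t tests."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = [l for l in pd.unique(labels)]
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    groups = [values[labels == l] for l in levels]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    grand = values.mean()
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b = len(levels) - 1
    df_w = values.size - len(levels)
    if ss_within == 0.0:
        f_stat = float("inf") if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    gstats = pd.DataFrame(
        {
            "level": levels,
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) for g in groups],
        }
    )
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    raw = []
    for a, b in pairs:
        ga, gb = values[labels == a], values[labels == b]
        if ga.std(ddof=1) == 0 and gb.std(ddof=1) == 0:
            raw.append(1.0 if ga.mean() == gb.mean() else 0.0)
        else:
            raw.append(float(stats.ttest_ind(ga, gb, equal_var=False).pvalue))
    adj = bonferroni(raw, len(pairs)) if pairs else []
    pairwise = pd.DataFrame(
        {
            "level_a": [a for a, _ in pairs],
            "level_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_bonferroni": adj,
        }
    )
    return EffectSummary(
        outcome=outcome,
        grouping=grouping,
        f_stat=float(f_stat),
        p_value=p,
        eta_sq_p=partial_eta_squared(ss_between, ss_within),
        ss_between=ss_between,
        ss_within=ss_within,
        group_stats=gstats,
        pairwise=pairwise,
    )


def q5_q1_ratio(q1_mean: float, q5_mean: float) -> float | None:
    """Fifth-to-first-quintile mean ratio, round-half-up to 2 decimals.

    Returns None (reported as an undefined marker) when the first-quintile
    mean is zero.
    """
    if q1_mean == 0:
        return None
    return round_half_up(q5_mean / q1_mean, 2)


def quintile_summary(
    usual: pd.DataFrame,
    quintiles: pd.DataFrame,
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Mean/SD of usual intake per pooled quintile and the Q5/Q1 ratio.

    Quintiles are the subgroup-assigned ones pooled across subgroups.  Rows
    are sorted by descending ratio within the healthy block, then the
    unhealthy block.
    """
    df = usual.merge(quintiles, on="subject_id")
    rows = []
    for f in factors:
        qcol = f"q_{f.name}"
        row: dict = {"factor": f.name, "direction": f.direction, "unit": f.unit}
        for q in range(1, 6):
            v = df.loc[df[qcol] == q, f.name]
            row[f"q{q}_n"] = int(len(v))
            row[f"q{q}_mean"] = float(v.mean()) if len(v) else float("nan")
            row[f"q{q}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        row["ratio_q5_q1"] = q5_q1_ratio(row["q1_mean"], row["q5_mean"])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["_sort"] = out["ratio_q5_q1"].astype(float)
    out = (
        out.sort_values(
            ["direction", "_sort"], ascending=[True, False], kind="mergesort"
        )
        .drop(columns="_sort")
        .reset_index(drop=True)
    )
    return out


def country_summary(
    usual: pd.DataFrame,
    subjects: pd.DataFrame,
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Per-country mean (SD) of 2000-kcal-adjusted usual intake per factor."""
    df = usual.merge(subjects[["subject_id", "country"]], on="subject_id")
    rows = []
    for f in factors:
        row: dict = {"factor": f.name, "direction": f.direction}
        row["all_mean"] = float(df[f.name].mean())
        row["all_sd"] = float(df[f.name].std(ddof=1))
        for c in COUNTRIES:
            v = df.loc[df["country"] == c, f.name]
            row[f"{c}_mean"] = float(v.mean()) if len(v) else float("nan")
            row[f"{c}_sd"] = float(v.std(ddof=1)) if len(v) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


SCORE_OUTCOMES = ("healthy_std", "unhealthy_std", "total_std", "dds")

STRATIFIER_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": SEXES,
    "age_group": AGE_GROUPS,
    "country": COUNTRIES,
    "sel": SELS,
    "bmi_class": BMI_CLASSES,
    "wc_class": ("below", "above"),
    "neck_class": ("below", "above"),
}


def score_strata_report(
    dqs: pd.DataFrame,
    dds_results: pd.DataFrame,
    subjects: pd.DataFrame,
    anthro_classes: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score means per stratum with per-stratifier ANOVA and post-hoc tests.

    Returns
    -------
    strata : DataFrame
        n, %, and mean (SD) of the three standardized DQS and the DDS for the
        total sample and every level of every stratifier (empty strata get
        n = 0 and empty statistics).
    effects : DataFrame
        Per (stratifier, outcome): F, p, partial eta-squared.
    pairwise : DataFrame
        Bonferroni-adjusted pairwise comparisons per (stratifier, outcome).
    """
    df = (
        subjects[["subject_id", "country", "sex", "age_group", "sel"]]
        .merge(dqs[["subject_id", "healthy_std", "unhealthy_std", "total_std"]], on="subject_id")
        .merge(dds_results[["subject_id", "dds"]], on="subject_id")
        .merge(anthro_classes[["subject_id", "bmi_class", "wc_class", "neck_class"]], on="subject_id", how="left")
    )
    n_total = len(df)

    def stat_block(sub: pd.DataFrame, stratifier: str, level: str) -> dict:
        row: dict = {
            "stratifier": stratifier,
            "level": level,
            "n": len(sub),
            "pct": 100.0 * len(sub) / n_total if n_total else float("nan"),
        }
        for out in SCORE_OUTCOMES:
            if len(sub):
                row[f"{out}_mean"] = float(sub[out].mean())
                row[f"{out}_sd"] = float(sub[out].std(ddof=1)) if len(sub) > 1 else float("nan")
            else:
                row[f"{out}_mean"] = float("nan")
                row[f"{out}_sd"] = float("nan")
        return row

    rows = [stat_block(df, "total", "all")]
    effect_rows, pair_rows = [], []
    for strat, levels in STRATIFIER_LEVELS.items():
        observed = [l for l in levels if (df[strat] == l).any()]
        for level in levels:
            rows.append(stat_block(df[df[strat] == level], strat, level))
        if len(observed) < 2:
            continue
        mask = df[strat].isin(observed)
        sizes = df.loc[mask, strat].value_counts()
        if (sizes < 2).any():
            continue
        for out in SCORE_OUTCOMES:
            eff = anova_oneway(
                df.loc[mask, out], df.loc[mask, strat], outcome=out, grouping=strat
            )
            effect_rows.append(
                {
                    "stratifier": strat,
                    "outcome": out,
                    "f_stat": eff.f_stat,
                    "p_value": eff.p_value,
                    "eta_sq_p": eff.eta_sq_p,
                }
            )
            pw = eff.pairwise.copy()
            pw.insert(0, "outcome", out)
            pw.insert(0, "stratifier", strat)
            pair_rows.append(pw)
    strata = pd.DataFrame(rows)
    effects = pd.DataFrame(effect_rows)
    pairwise = (
        pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame()
    )
    return strata, effects, pairwise


@dataclass
class RegressionSummary:
    """OLS fit of a score outcome on score predictors."""

    outcome: str
    predictors: tuple[str, ...]
    stratum: str
    n: int
    r: float
    r_squared: float
    coefficients: dict[str, float] = field(default_factory=dict)
    collinear: bool = False


def regress_scores(
    data: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...],
    strata: str | None = None,
) -> list[RegressionSummary]:
    """OLS of ``outcome`` on ``predictors``, overall and per stratum level.

    The multiple correlation R is reported as sqrt(R^2).  Exactly collinear
    predictors are flagged and their coefficients suppressed.
    """
    blocks: list[tuple[str, pd.DataFrame]] = [("all", data)]
    if strata is not None:
        blocks += [
            (str(level), grp)
            for level, grp in data.groupby(strata, sort=True, observed=True)
        ]
    out: list[RegressionSummary] = []
    for label, block in blocks:
        n = len(block)
        if n <= len(predictors) + 1:
            raise ValueError(
                f"stratum {label!r}: n={n} too small for {len(predictors)} predictors"
            )
        X = block[list(predictors)].to_numpy(dtype=float)
        collinear = np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < X.shape[1] + 1
        y = block[outcome].to_numpy(dtype=float)
        fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        r2 = float(fit.rsquared)
        out.append(
            RegressionSummary(
                outcome=outcome,
                predictors=tuple(predictors),
                stratum=label,
                n=n,
                r=float(np.sqrt(max(r2, 0.0))),
                r_squared=r2,
                coefficients=(
                    {}
                    if collinear
                    else {p: float(b) for p, b in zip(("const",) + tuple(predictors), fit.params)}
                ),
                collinear=bool(collinear),
            )
        )
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its p-value."""
    r, p = stats.pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return float(r), float(p)


def format_p(p: float) -> str:
    """Report p to 4 decimals; below 1e-4 print "<0.0001"."""
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4f}"
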