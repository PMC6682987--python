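"""Quintile-based Diet Quality Scores (healthy / unhealthy / total).

Within each of the 64 (country, sex, age band) subgroups, subjects are ranked
by usual intake of a factor and split into five consecutive near-equal blocks
(quintiles).  An ordinal item score 1-5 follows: for healthy factors the score
is the quintile itself (highest intake scores 5); for unhealthy factors it is
reversed (lowest intake scores 5).  Summing item scores gives

* healthy DQS, 10 items, range 10-50;
* unhealthy DQS, 7 items, range 7-35;
* total DQS = their sum, range 17-85;

each standardized to a 100-point scale as 100 x raw / maximum.

Quintile construction details (fixed, documented conventions):

* rank blocks, not value cut-points -- heavy ties (zero consumers of nuts or
  fish) would otherwise produce wildly unequal quintile sizes;
* n = 5k + r puts the extra member into each of the r lowest quintiles, so
  block sizes differ by at most one;
* ties broken deterministically by ascending subject_id (a seeded random
  tie-break is available as an alternative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_FACTORS,
    FactorDef,
    HEALTHY_FACTOR_NAMES,
    UNHEALTHY_FACTOR_NAMES,
    ValidationError,
)

MAX_HEALTHY_RAW = 5 * len(HEALTHY_FACTOR_NAMES)  # 50
MAX_UNHEALTHY_RAW = 5 * len(UNHEALTHY_FACTOR_NAMES)  # 35
MAX_TOTAL_RAW = MAX_HEALTHY_RAW + MAX_UNHEALTHY_RAW  # 85


def quintile_sizes(n: int) -> list[int]:
    """Block sizes for n subjects: remainder goes to the lowest quintiles."""
    base, r = divmod(n, 5)
    return [base + 1 if i < r else base for i in range(5)]


def assign_quintiles(
    usual: pd.DataFrame,
    subjects: pd.DataFrame,
    factor: str,
    min_subgroup_size: int = 5,
    tie_break: str = "subject_id",
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Assign each subject a quintile (1 = lowest intake) within its subgroup.

    Parameters
    ----------
    usual : DataFrame with subject_id and a column per factor.
    subjects : DataFrame with subject_id, country, sex, age_group.
    factor : which factor column to rank.
    tie_break : "subject_id" (deterministic, default) or "random" (requires rng).
    """
    if factor not in usual.columns:
        raise ValidationError(f"usual-intake table lacks factor {factor!r}")
    df = usual[["subject_id", factor]].merge(
        subjects[["subject_id", "country", "sex", "age_group"]],
        on="subject_id",
    )
    if df[factor].isna().any():
        bad = df.loc[df[factor].isna(), "subject_id"].iloc[0]
        raise ValidationError(f"missing usual intake of {factor!r} for {bad!r}")
    if tie_break == "random":
        if rng is None:
            raise ValueError("random tie-break requires an rng")
        df["_tie"] = rng.permutation(len(df))
    elif tie_break == "subject_id":
        df["_tie"] = df["subject_id"]
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")

    out = pd.Series(0, index=pd.Index(df["subject_id"], name="subject_id"), dtype=int)
    for key, grp in df.groupby(["country", "sex", "age_group"], sort=True, observed=True):
        n = len(grp)
        if n < min_subgroup_size:
            raise ValidationError(
                f"subgroup {key} has {n} subjects (< {min_subgroup_size})"
            )
        order = grp.sort_values([factor, "_tie"], kind="mergesort")
        q = np.repeat(np.arange(1, 6), quintile_sizes(n))
        out.loc[order["subject_id"].to_numpy()] = q
    return out


def assign_all_quintiles(
    usual: pd.DataFrame,
    subjects: pd.DataFrame,
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS,
    min_subgroup_size: int = 5,
    tie_break: str = "subject_id",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Quintiles for every factor; columns ``q_<factor>`` indexed like usual."""
    cols = {
        f"q_{f.name}": assign_quintiles(
            usual, subjects, f.name, min_subgroup_size, tie_break, rng
        )
        for f in factors
    }
    qt = pd.DataFrame(cols).reset_index()
    return qt


def score_item(q: int, direction: str) -> int:
    """Item score from a quintile: healthy -> q, unhealthy -> 6 - q."""
    if not 1 <= q <= 5:
        raise ValueError(f"quintile must be in 1..5, got {q}")
    if direction == "healthy":
        return int(q)
    if direction == "unhealthy":
        return int(6 - q)
    raise ValueError(f"unknown direction {direction!r}")


def compute_dqs(
    quintiles: pd.DataFrame,
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Sum item scores into raw and standardized healthy/unhealthy/total DQS.

    ``quintiles`` must carry subject_id and a ``q_<factor>`` column per factor.
    """
    missing = [f.name for f in factors if f"q_{f.name}" not in quintiles.columns]
    if missing:
        raise ValidationError(f"missing quintile columns for factors: {missing}")
    healthy = np.zeros(len(quintiles), dtype=int)
    unhealthy = np.zeros(len(quintiles), dtype=int)
    for f in factors:
        q = quintiles[f"q_{f.name}"].to_numpy(dtype=int)
        if ((q < 1) | (q > 5)).any():
            raise ValidationError(f"quintile out of range for {f.name}")
        if f.direction == "healthy":
            healthy += q
        else:
            unhealthy += 6 - q
    out = pd.DataFrame({"subject_id": quintiles["subject_id"]})
    out["healthy_raw"] = healthy
    out["unhealthy_raw"] = unhealthy
    out["total_raw"] = healthy + unhealthy
    out["healthy_std"] = 100.0 * healthy / MAX_HEALTHY_RAW
    out["unhealthy_std"] = 100.0 * unhealthy / MAX_UNHEALTHY_RAW
    out["total_std"] = 100.0 * out["total_raw"] / MAX_TOTAL_RAW
    return out
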