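"""Usual-intake estimation from two 24-h recalls, with 2000-kcal adjustment.

A single 24-h recall mixes a subject's long-run mean intake with day-to-day
noise.  With two recall days per subject the day-to-day (within-person)
variance can be separated from the between-person variance inside each of the
64 (country, sex, age band) subgroups, and each subject's day mean can be
shrunk toward the subgroup mean -- the same role the Multiple Source Method
plays in large surveys, reduced to its shrinkage essence:

1. energy-adjust each day's g/d and mg/d amounts to a 2000 kcal basis
   (amount x 2000 / that day's energy); % energy factors are already
   energy-normalized and pass through;
2. transform day values with log(x + c), c = half the smallest positive
   observed value in the (subgroup, factor) cell (keeps zero days finite);
3. estimate between-person (sigma2_b) and within-person (sigma2_w) variance
   components by one-way random-effects ANOVA of day values on subjects
   (method of moments; negative sigma2_b truncated to 0);
4. shrink each subject's day mean toward the subgroup mean of day means with
   lambda_i = sigma2_b / (sigma2_b + sigma2_w / n_i);
5. back-transform with exp(.) - c (optionally with a multiplicative
   lognormal bias correction, off by default).

Subjects with a single recall day are retained (n_i = 1, hence stronger
shrinkage).  A subgroup with no 2-day subject cannot separate the variance
components and falls back to raw subject means with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_FACTORS, FactorDef, ValidationError

REFERENCE_KCAL = 2000.0


def adjust_to_2000kcal(amount: float, energy_kcal: float, unit: str = "g/d") -> float:
    """Scale a g/d or mg/d amount to a 2000 kcal/day basis.

    % energy factors are already energy-normalized; passing one is a
    contract violation, not a silent no-op.
    """
    if unit == "%energy":
        raise ValueError("% energy factors must not be energy-adjusted")
    if energy_kcal <= 0:
        raise ValueError(f"energy must be positive, got {energy_kcal}")
    return amount * REFERENCE_KCAL / energy_kcal


@dataclass
class UsualIntakeOptions:
    """Estimator switches.

    transform
        "log" (default) shrinks on the log(x + c) scale; "none" shrinks on
        the raw scale (exact mean preservation and variance reduction on the
        original scale -- useful for checking the estimator's algebra).
    shrink
        False returns each subject's plain day mean (no pooling).
    bias_correction
        Multiply back-transformed values by exp(sigma2_w * (1 - lambda) / 2),
        the lognormal mean correction for the residual shrinkage noise.
    two_part
        Episodic factors: model consumption probability and consumption-day
        amount separately, usual = p_hat x usual(consumption days).
    """

    transform: str = "log"
    shrink: bool = True
    bias_correction: bool = False
    two_part: bool = False

    def __post_init__(self) -> None:
        if self.transform not in ("log", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ShrinkageFit:
    """Variance components and shrinkage weights for one (subgroup, factor)."""

    sigma2_b: float
    sigma2_w: float
    c_offset: float
    n_subjects: int
    fallback: bool  # True when components could not be estimated
    lambda_by_n: dict[int, float]


def _variance_components(t: np.ndarray, sid: np.ndarray) -> tuple[float, float, float, bool]:
    """Method-of-moments one-way random-effects decomposition.

    Returns (sigma2_b, sigma2_w, n0, fallback) where n0 is the effective
    replicates-per-subject constant for unbalanced designs.
    """
    ids, inv, counts = np.unique(sid, return_inverse=True, return_counts=True)
    k = ids.size
    N = t.size
    means = np.bincount(inv, weights=t) / counts
    df_within = N - k
    if k < 2 or df_within < 1:
        return 0.0, 0.0, 1.0, True
    ssw = float(np.sum((t - means[inv]) ** 2))
    msw = ssw / df_within
    grand = float(t.mean())
    ssb = float(np.sum(counts * (means - grand) ** 2))
    msb = ssb / (k - 1)
    n0 = (N - float(np.sum(counts**2)) / N) / (k - 1)
    sigma2_b = max(0.0, (msb - msw) / n0)
    return sigma2_b, msw, n0, False


def estimate_usual(
    day_values: pd.DataFrame,
    factor: FactorDef | None = None,
    options: UsualIntakeOptions | None = None,
) -> tuple[pd.Series, ShrinkageFit]:
    """Estimate per-subject usual intake within one subgroup.

    Parameters
    ----------
    day_values : DataFrame
        Columns ``subject_id`` and ``value`` -- one row per recall day, with
        values already energy-adjusted where applicable.
    factor : FactorDef, optional
        Only consulted by the two-part episodic mode.
    options : UsualIntakeOptions

    Returns
    -------
    usual : Series indexed by subject_id.
    fit : ShrinkageFit with the variance components actually used.
    """
    opts = options or UsualIntakeOptions()
    if opts.two_part and factor is not None and factor.episodic:
        return _estimate_two_part(day_values, factor, opts)

    sid = day_values["subject_id"].to_numpy()
    x = day_values["value"].to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("negative day value in usual-intake estimation")
    ids, inv, counts = np.unique(sid, return_inverse=True, return_counts=True)
    raw_means = np.bincount(inv, weights=x) / counts

    if not opts.shrink:
        fit = ShrinkageFit(0.0, 0.0, 0.0, ids.size, True, {int(c): 1.0 for c in set(counts)})
        return pd.Series(raw_means, index=pd.Index(ids, name="subject_id")), fit

    pos = x[x > 0]
    c = 0.5 * float(pos.min()) if pos.size else 0.0
    if opts.transform == "log":
        if pos.size == 0:
            # all-zero cell: the constant is everyone's usual intake
            fit = ShrinkageFit(0.0, 0.0, 0.0, ids.size, False, {int(n): 1.0 for n in set(counts)})
            return pd.Series(raw_means, index=pd.Index(ids, name="subject_id")), fit
        t = np.log(x + c)
    else:
        c = 0.0
        t = x

    sigma2_b, sigma2_w, _, fallback = _variance_components(t, sid)
    t_means = np.bincount(inv, weights=t) / counts
    if fallback:
        usual = raw_means
        lam = {int(n): 1.0 for n in set(counts)}
    else:
        denom = sigma2_b + sigma2_w / counts
        with np.errstate(invalid="ignore", divide="ignore"):
            lam_i = np.where(denom > 0, sigma2_b / np.where(denom > 0, denom, 1.0), 1.0)
        if sigma2_b == 0.0 and sigma2_w == 0.0:
            lam_i = np.ones_like(lam_i)
        mu = float(t_means.mean())
        shrunk = mu + lam_i * (t_means - mu)
        if opts.transform == "log":
            usual = np.exp(shrunk) - c
            if opts.bias_correction:
                usual = (np.exp(shrunk + sigma2_w * (1.0 - lam_i) / 2.0)) - c
            usual = np.maximum(usual, 0.0)
        else:
            usual = shrunk
        lam = {int(n): float(sigma2_b / (sigma2_b + sigma2_w / n)) if (sigma2_b + sigma2_w / n) > 0 else 1.0
               for n in set(counts)}
    fit = ShrinkageFit(float(sigma2_b), float(sigma2_w), c, ids.size, fallback, lam)
    return pd.Series(usual, index=pd.Index(ids, name="subject_id")), fit


def _estimate_two_part(
    day_values: pd.DataFrame, factor: FactorDef, opts: UsualIntakeOptions
) -> tuple[pd.Series, ShrinkageFit]:
    """Two-part episodic model: P(consumption) x usual consumption-day amount."""
    x = day_values["value"].to_numpy(dtype=float)
    p_hat = float((x > 0).mean())
    if p_hat == 0.0:
        sid = np.unique(day_values["subject_id"].to_numpy())
        fit = ShrinkageFit(0.0, 0.0, 0.0, sid.size, False, {})
        return pd.Series(0.0, index=pd.Index(sid, name="subject_id")), fit
    consumption = day_values[day_values["value"] > 0]
    amount_opts = UsualIntakeOptions(
        transform=opts.transform, shrink=opts.shrink,
        bias_correction=opts.bias_correction, two_part=False,
    )
    usual_amount, fit = estimate_usual(consumption, factor, amount_opts)
    all_ids = np.unique(day_values["subject_id"].to_numpy())
    # subjects never observed consuming carry no amount information; give
    # them the pooled consumption-day usual amount rather than zero
    usual = usual_amount.reindex(all_ids).fillna(float(usual_amount.mean())) * p_hat
    usual.index.name = "subject_id"
    return usual, fit


def build_usual_table(
    subjects: pd.DataFrame,
    recalls: pd.DataFrame,
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS,
    options: UsualIntakeOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate usual intake of every factor for every subject.

    Energy adjustment is applied to each day's g/d and mg/d amounts before
    estimation (per-day density method); % energy factors pass through.
    Estimation runs independently per (country, sex, age band) subgroup and
    factor.

    Returns
    -------
    usual : DataFrame
        One row per subject: subject_id + one column per factor.
    meta : DataFrame
        One row per (subgroup, factor): variance components, offset,
        shrinkage weight for 2-day subjects, and fallback flag.
    """
    opts = options or UsualIntakeOptions()
    missing = set(subjects["subject_id"]) - set(recalls["subject_id"])
    if missing:
        raise ValidationError(
            f"subjects with zero recall days: {sorted(missing)[:5]}"
        )
    key_cols = ["country", "sex", "age_group"]
    rec = recalls.merge(
        subjects[["subject_id"] + key_cols], on="subject_id", how="left", sort=False
    )
    if rec[key_cols].isna().any().any():
        orphan = rec.loc[rec["country"].isna(), "subject_id"].iloc[0]
        raise ValidationError(f"recall rows for unknown subject {orphan!r}")

    energy = rec["energy_kcal"].to_numpy(dtype=float)
    usual_cols: dict[str, pd.Series] = {}
    meta_rows: list[dict] = []
    for f in factors:
        vals = rec[f.name].to_numpy(dtype=float)
        if f.unit in ("g/d", "mg/d"):
            vals = vals * REFERENCE_KCAL / energy
        work = pd.DataFrame(
            {
                "subject_id": rec["subject_id"],
                "country": rec["country"],
                "sex": rec["sex"],
                "age_group": rec["age_group"],
                "value": vals,
            }
        )
        parts: list[pd.Series] = []
        for key, grp in work.groupby(key_cols, sort=True, observed=True):
            est, fit = estimate_usual(grp, f, opts)
            parts.append(est)
            meta_rows.append(
                {
                    "country": key[0],
                    "sex": key[1],
                    "age_group": key[2],
                    "factor": f.name,
                    "sigma2_b": fit.sigma2_b,
                    "sigma2_w": fit.sigma2_w,
                    "c_offset": fit.c_offset,
                    "n_subjects": fit.n_subjects,
                    "lambda_2day": fit.lambda_by_n.get(2, float("nan")),
                    "fallback": fit.fallback,
                }
            )
        usual_cols[f.name] = pd.concat(parts)
    usual = pd.DataFrame(usual_cols)
    usual = usual.loc[subjects["subject_id"]].reset_index()
    meta = pd.DataFrame(meta_rows)
    return usual, meta
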