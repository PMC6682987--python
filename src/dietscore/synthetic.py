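"""Synthetic survey populations with the marginal structure of ELANS.

No subject-level microdata were released for the ELANS survey, so the
pipeline is exercised on simulated populations whose marginals match the
published summaries: 8 countries x 2 sexes x 4 age bands x 3 socio-economic
levels, two non-consecutive 24-h recalls per subject, per-country usual-intake
means/SDs for the 17 dietary factors, and food-group consumption frequencies.

The generative model, per subject and factor:

* latent usual intake ~ lognormal, moment-matched to the country's published
  (mean, SD) on the 2000-kcal-adjusted scale, with a socio-economic mean
  multiplier on healthy factors;
* each recall day's adjusted amount = latent x lognormal noise with a fixed
  within-person CV (mean-1 noise), so the latent value is the subject's true
  long-run mean;
* episodic factors are zeroed on a day with probability 1 - p_consume, and
  consumption-day amounts are divided by p_consume so the latent mean is
  preserved;
* the raw (as-eaten) amount stored in the recall file is the adjusted amount
  scaled by that day's energy / 2000 for g/d and mg/d factors; % energy
  factors are generated directly as percentages;
* each diversity group independently reaches the 15-g threshold with its
  configured probability.

A truth table records every latent usual intake for recovery tests.
Identical spec + seed => byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .core import (
    AGE_BAND_EDGES,
    AGE_GROUPS,
    COUNTRIES,
    DEFAULT_FACTORS,
    FACTOR_NAMES,
    FactorDef,
    SCHEMES,
    SELS,
    SEXES,
    group_columns,
)

REFERENCE_KCAL = 2000.0


def _default_group_probs(scheme: str) -> dict[str, float]:
    if scheme == "wdds9":
        return dict(reference.WDDS9_GROUP_PROBS)
    if scheme == "hdds9":
        return dict(reference.HDDS9_GROUP_PROBS)
    raise ValueError(f"unknown diversity scheme {scheme!r}")


@dataclass
class GeneratorSpec:
    """Study conditions for one simulated population.

    ``subjects_per_cell`` fills every (country, sex, age band, SEL) cell
    equally; ``country_totals`` instead fixes each country's total (the
    published per-country sample sizes) and spreads it over the country's 24
    cells as evenly as possible, remainders going to the earliest cells in
    the canonical (sex, age band, SEL) order.
    """

    subjects_per_cell: int = 5
    country_totals: Mapping[str, int] | None = None
    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS
    factor_stats: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: reference.COUNTRY_FACTOR_STATS
    )
    within_cv: float = 0.3
    episodic_prob: float = 0.6
    sel_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"high": 1.10, "middle": 1.00, "low": 0.90}
    )
    scheme: str = "wdds9"
    group_probs: Mapping[str, float] | None = None
    group_threshold_g: float = 15.0
    energy_mean: float = 2000.0
    energy_sd: float = 400.0
    energy_min: float = 800.0
    weekday_prob: float = 5.0 / 7.0
    seed: int = 0

    def resolved_group_probs(self) -> dict[str, float]:
        probs = _default_group_probs(self.scheme)
        if self.group_probs:
            probs.update(self.group_probs)
        bad = [g for g, p in probs.items() if not 0.0 <= p <= 1.0]
        if bad:
            raise ValueError(f"group probabilities outside [0,1]: {bad}")
        return probs

    def cell_counts(self) -> pd.DataFrame:
        """One row per (country, sex, age_group, sel) with its subject count."""
        rows = []
        if self.country_totals is not None:
            for country in COUNTRIES:
                total = int(self.country_totals.get(country, 0))
                cells = [(s, a, l) for s in SEXES for a in AGE_GROUPS for l in SELS]
                base, rem = divmod(total, len(cells))
                for idx, (s, a, l) in enumerate(cells):
                    rows.append((country, s, a, l, base + (1 if idx < rem else 0)))
        else:
            if self.subjects_per_cell < 0:
                raise ValueError("subjects_per_cell must be >= 0")
            for country in COUNTRIES:
                for s in SEXES:
                    for a in AGE_GROUPS:
                        for l in SELS:
                            rows.append((country, s, a, l, self.subjects_per_cell))
        df = pd.DataFrame(rows, columns=["country", "sex", "age_group", "sel", "n"])
        if df["n"].sum() == 0:
            raise ValueError("generator spec produces an empty population")
        return df


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError(f"nonpositive mean {mean} with positive SD")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _mean_one_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def _simulate_anthropometry(
    rng: np.random.Generator, sex: np.ndarray, age: np.ndarray
) -> dict[str, np.ndarray]:
    male = sex == "male"
    n = sex.size
    height = np.where(male, 171.0, 158.5) + rng.normal(0.0, 6.8, n)
    bmi = np.clip(rng.normal(27.0, 4.6, n), 15.5, 55.0)
    weight = bmi * (height / 100.0) ** 2
    wc = 45.0 + 1.65 * bmi + np.where(male, 4.0, 0.0) + rng.normal(0.0, 5.0, n)
    neck = (
        np.where(male, 38.0, 33.3)
        + 0.18 * (bmi - 27.0)
        + rng.normal(0.0, 2.2, n)
    )
    return {
        "weight_kg": np.round(weight, 1),
        "height_cm": np.round(height, 1),
        "wc_cm": np.round(np.clip(wc, 50.0, None), 1),
        "neck_cm": np.round(np.clip(neck, 25.0, None), 1),
    }


def _adolescent_flag(bmi: np.ndarray) -> np.ndarray:
    """Synthetic stand-in for the precomputed adolescent BMI-for-age category.

    Real data would carry WHO-2007 BMI-for-age classifications computed
    upstream; the simulator approximates them with the adult bands so that
    downstream code always sees a populated flag for under-18 subjects.
    """
    return np.select(
        [bmi <= 18.5, bmi < 25.0, bmi < 30.0],
        ["underweight", "normal", "overweight"],
        default="obese",
    )


def generate_population(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (subjects, recalls, truth) tables for one study population.

    Returns
    -------
    subjects : DataFrame
        One row per subject with demographics and anthropometry.
    recalls : DataFrame
        Two rows per subject (recall_index 1 and 2) with energy, raw factor
        amounts, and diversity-group grams.
    truth : DataFrame
        One row per subject with the latent (2000-kcal-adjusted) usual intake
        of every factor -- the quantity the usual-intake estimator targets.
    """
    rng = np.random.default_rng(spec.seed)
    cells = spec.cell_counts()
    factors = spec.factors
    group_probs = spec.resolved_group_probs()
    groups = SCHEMES[spec.scheme]
    if set(group_probs) != set(groups):
        raise ValueError("group probabilities do not match the scheme's groups")

    # --- subjects ---------------------------------------------------------
    country = np.repeat(cells["country"].to_numpy(), cells["n"].to_numpy())
    sex = np.repeat(cells["sex"].to_numpy(), cells["n"].to_numpy())
    band = np.repeat(cells["age_group"].to_numpy(), cells["n"].to_numpy())
    sel = np.repeat(cells["sel"].to_numpy(), cells["n"].to_numpy())
    n = country.size
    subject_id = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    lo = np.array([AGE_BAND_EDGES[b][0] for b in band])
    hi = np.array([AGE_BAND_EDGES[b][1] for b in band])
    age = rng.integers(lo, hi + 1)
    anthro = _simulate_anthropometry(rng, sex, age)
    bmi = anthro["weight_kg"] / (anthro["height_cm"] / 100.0) ** 2
    flag = np.where(age < 18, _adolescent_flag(bmi), "")
    subjects = pd.DataFrame(
        {
            "subject_id": subject_id,
            "country": country,
            "sex": sex,
            "age_years": age,
            "sel": sel,
            **anthro,
            "bmi_for_age_flag": flag,
        }
    )
    subjects["age_group"] = band

    # --- latent usual intakes --------------------------------------------
    truth = pd.DataFrame({"subject_id": subject_id, "country": country})
    sel_mult = np.array([spec.sel_multipliers[s] for s in sel])
    latent: dict[str, np.ndarray] = {}
    for f in factors:
        stats_by_country = spec.factor_stats[f.name]
        vals = np.empty(n)
        for c in COUNTRIES:
            mask = country == c
            if not mask.any():
                continue
            mean, sd = stats_by_country[c]
            m = mean * (sel_mult[mask] if f.direction == "healthy" else 1.0)
            if sd == 0:
                vals[mask] = m
            else:
                # moment-match each subject's (possibly SEL-shifted) mean; the
                # SEL multiplier scales SD proportionally (constant CV).
                if mean <= 0:
                    raise ValueError(
                        f"nonpositive mean for {f.name} in {c} with positive SD"
                    )
                sigma2 = np.log1p((sd / mean) ** 2)
                mu = np.log(m) - sigma2 / 2.0
                vals[mask] = rng.lognormal(mu, np.sqrt(sigma2), int(mask.sum()))
        latent[f.name] = vals
        truth[f.name] = vals

    # --- recall days -------------------------------------------------------
    rec_sid = np.repeat(subject_id, 2)
    rec_index = np.tile([1, 2], n)
    day_type = np.where(
        rng.random(2 * n) < spec.weekday_prob, "weekday", "weekend"
    )
    a = (spec.energy_min - spec.energy_mean) / spec.energy_sd
    energy = stats.truncnorm.rvs(
        a, np.inf, loc=spec.energy_mean, scale=spec.energy_sd,
        size=2 * n, random_state=rng,
    )
    recalls = pd.DataFrame(
        {
            "subject_id": rec_sid,
            "recall_index": rec_index,
            "day_type": day_type,
            "energy_kcal": np.round(energy, 1),
        }
    )
    for f in factors:
        day_adj = np.repeat(latent[f.name], 2) * _mean_one_noise(
            rng, spec.within_cv, 2 * n
        )
        if f.episodic:
            p = spec.episodic_prob
            consumed = rng.random(2 * n) < p
            day_adj = np.where(consumed, day_adj / p, 0.0)
        if f.unit == "%energy":
            raw = day_adj
        else:
            raw = day_adj * recalls["energy_kcal"].to_numpy() / REFERENCE_KCAL
        recalls[f.name] = np.round(raw, 4)
    for g in groups:
        p = group_probs[g]
        consumed = rng.random(2 * n) < p
        over = spec.group_threshold_g + rng.gamma(2.0, 25.0, 2 * n)
        # keep sub-threshold draws strictly below the threshold after rounding
        under = rng.uniform(0.0, spec.group_threshold_g - 0.011, 2 * n)
        recalls[f"grp_{g}"] = np.round(np.where(consumed, over, under), 2)
    return subjects, recalls, truth


def summarize_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-(country, factor) empirical mean and SD of latent usual intake.

    SD is left empty for a single-subject cell (sample SD undefined).
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    fcols = [c for c in truth.columns if c in FACTOR_NAMES]
    rows = []
    for c, grp in truth.groupby("country", sort=True):
        for f in fcols:
            v = grp[f].to_numpy()
            rows.append(
                {
                    "country": c,
                    "factor": f,
                    "n": v.size,
                    "mean": float(v.mean()),
                    "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
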