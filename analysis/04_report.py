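#!/usr/bin/env python
"""Produce the survey-style report tables.

Writes to results/: the quintile summary with Q5/Q1 ratios (table1), the
per-country usual-intake means (table2), score means stratified by
demographics and anthropometry with ANOVA effect sizes (table3 +
anova_effects + posthoc), food-group consumption frequencies per DDS tertile
(fig1), and the score regressions.
"""

import argparse
from pathlib import Path

import pandas as pd

from dietscore.core import load_subjects, write_table
from dietscore.dds import group_frequencies
from dietscore.dqs import assign_all_quintiles
from dietscore.report import (
    country_summary,
    format_p,
    quintile_summary,
    regress_scores,
    score_strata_report,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--scheme", choices=["hdds9", "wdds9"], default="wdds9")
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    subjects = load_subjects(args.data_dir / "subjects.csv")
    usual = pd.read_csv(args.data_dir / "usual.csv", dtype={"subject_id": str})
    dqs = pd.read_csv(args.data_dir / "dqs.csv", dtype={"subject_id": str})
    dds = pd.read_csv(args.data_dir / "dds.csv", dtype={"subject_id": str})
    anthro = pd.read_csv(args.data_dir / "anthro.csv", dtype={"subject_id": str})

    quintiles = dqs[["subject_id"] + [c for c in dqs.columns if c.startswith("q_")]]
    t1 = quintile_summary(usual, quintiles)
    write_table(t1, args.results / "table1_quintiles.csv")
    top = t1.iloc[0]
    print(f"largest Q5/Q1 contrast: {top['factor']} at {top['ratio_q5_q1']}-fold")

    write_table(country_summary(usual, subjects), args.results / "table2_countries.csv")

    strata, effects, pairwise = score_strata_report(dqs, dds, subjects, anthro)
    write_table(strata, args.results / "table3_strata.csv")
    effects = effects.assign(p_display=[format_p(p) for p in effects["p_value"]])
    write_table(effects, args.results / "anova_effects.csv", precision=4)
    write_table(pairwise, args.results / "posthoc_pairwise.csv", precision=4)

    freq_all = group_frequencies(dds, scheme=args.scheme)
    freq_t = group_frequencies(dds, scheme=args.scheme, by_tertile=True)
    write_table(pd.concat([freq_all, freq_t], ignore_index=True),
                args.results / "fig1_group_frequencies.csv")

    scores = dqs.merge(dds[["subject_id", "dds"]], on="subject_id").merge(
        subjects[["subject_id", "sex", "sel", "country"]], on="subject_id"
    )
    fits = (
        regress_scores(scores, "total_std", ("healthy_std",))
        + regress_scores(scores, "total_std", ("unhealthy_std",))
        + regress_scores(scores, "total_raw", ("healthy_raw", "unhealthy_raw"))
        + regress_scores(scores, "dds", ("healthy_std",), strata="sex")
        + regress_scores(scores, "dds", ("healthy_std",), strata="sel")
        + regress_scores(scores, "dds", ("healthy_std",), strata="country")
    )
    rows = [
        {"outcome": f.outcome, "predictors": "+".join(f.predictors),
         "stratum": f.stratum, "n": f.n, "r": f.r, "r_squared": f.r_squared}
        for f in fits
    ]
    write_table(pd.DataFrame(rows), args.results / "regressions.csv", precision=4)

    sel_rows = strata[strata["stratifier"] == "sel"].set_index("level")
    print("healthy DQS by SEL:",
          ", ".join(f"{l}={sel_rows.loc[l, 'healthy_std_mean']:.1f}%"
                    for l in ("high", "middle", "low")))
    h = next(f for f in fits if f.outcome == "total_std" and f.predictors == ("healthy_std",))
    u = next(f for f in fits if f.outcome == "total_std" and f.predictors == ("unhealthy_std",))
    print(f"variance in total DQS explained: healthy R^2={h.r_squared:.2f}, "
          f"unhealthy R^2={u.r_squared:.2f}")


if __name__ == "__main__":
    main()
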