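#!/usr/bin/env python
"""Score diet quality and diversity, and classify anthropometry.

Assigns within-subgroup quintiles of usual intake for the 17 factors, sums
them into the healthy / unhealthy / total Diet Quality Scores, scores the 0-9
Diet Diversity Score from the first recall day (15-g rule), and classifies
BMI, waist and neck circumference.
"""

import argparse
from pathlib import Path

import pandas as pd

from dietscore.anthro import classify_subjects
from dietscore.core import load_recalls, load_subjects, write_data
from dietscore.dds import compute_dds
from dietscore.dqs import assign_all_quintiles, compute_dqs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/analysis"))
    ap.add_argument("--scheme", choices=["hdds9", "wdds9"], default="wdds9")
    args = ap.parse_args()

    subjects = load_subjects(args.data_dir / "subjects.csv")
    recalls = load_recalls(args.data_dir / "recalls.csv", scheme=args.scheme)
    usual = pd.read_csv(args.data_dir / "usual.csv", dtype={"subject_id": str})

    quintiles = assign_all_quintiles(usual, subjects)
    dqs = compute_dqs(quintiles)
    write_data(quintiles.merge(dqs, on="subject_id"), args.data_dir / "dqs.csv")

    dds = compute_dds(recalls, scheme=args.scheme)
    write_data(dds, args.data_dir / "dds.csv")

    anthro = classify_subjects(subjects)
    write_data(anthro, args.data_dir / "anthro.csv")

    print(f"total DQS {dqs['total_std'].mean():.1f}% +/- {dqs['total_std'].std():.1f}% "
          f"(healthy {dqs['healthy_std'].mean():.1f}%, "
          f"unhealthy {dqs['unhealthy_std'].mean():.1f}%); "
          f"DDS {dds['dds'].mean():.2f} +/- {dds['dds'].std():.2f} of 9")


if __name__ == "__main__":
    main()
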