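#!/usr/bin/env python
"""Simulate the study population.

Generates a synthetic eight-country survey population at the published
per-country sample sizes (9218 subjects, two 24-h recalls each) and writes
subjects.csv, recalls.csv and the latent truth table.  Bulky subject-level
data go to the scratch directory; downstream steps read them from there.
"""

import argparse
from pathlib import Path

from dietscore.core import write_data
from dietscore.reference import COUNTRY_SAMPLE_SIZES
from dietscore.synthetic import GeneratorSpec, generate_population


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/analysis"))
    args = ap.parse_args()

    spec = GeneratorSpec(country_totals=COUNTRY_SAMPLE_SIZES, seed=args.seed)
    subjects, recalls, truth = generate_population(spec)
    args.data_dir.mkdir(parents=True, exist_ok=True)
    write_data(subjects, args.data_dir / "subjects.csv")
    write_data(recalls, args.data_dir / "recalls.csv")
    write_data(truth, args.data_dir / "truth.csv")
    print(f"simulated {len(subjects)} subjects across "
          f"{subjects['country'].nunique()} countries "
          f"({len(recalls)} recall days) -> {args.data_dir}")


if __name__ == "__main__":
    main()
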