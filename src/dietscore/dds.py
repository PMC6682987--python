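"""Diet Diversity Score: 9 food groups, a 15-g rule, and tertile bands.

The DDS counts the food groups (out of nine) from which a subject consumed at
least 15 g on the day covered by the first 24-h recall.  Two 9-group schemes
are supported -- the household-style grouping ("hdds9") and the women's
diversity project grouping ("wdds9") -- and input files must carry the active
scheme's nine ``grp_*`` columns.

Tertile bands over the integer scores: band 1 is 0-4 points, band 2 is
exactly 5, band 3 is 6 or more (the published band labels leave 6 itself
unnamed; assigning it to the top band makes the bands partition 0..9).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .core import SCHEMES, ValidationError, group_columns


def score_day(group_grams: Mapping[str, float], threshold: float = 15.0) -> tuple[dict[str, int], int]:
    """Per-group indicators (grams >= threshold, inclusive) and their sum."""
    indicators = {g: int(v >= threshold) for g, v in group_grams.items()}
    return indicators, sum(indicators.values())


def dds_tertile(dds: int) -> int:
    """Tertile band of an integer DDS: <=4 -> 1, ==5 -> 2, >=6 -> 3."""
    if not 0 <= dds <= 9:
        raise ValueError(f"DDS must be in 0..9, got {dds}")
    if dds <= 4:
        return 1
    if dds == 5:
        return 2
    return 3


def compute_dds(
    recalls: pd.DataFrame,
    scheme: str = "hdds9",
    threshold: float = 15.0,
    day: int = 1,
    allow_any_day: bool = False,
) -> pd.DataFrame:
    """Score the DDS from one recall day for every subject.

    By default only recall day 1 is used (the day the diversity instrument
    refers to); pass ``day=2`` with ``allow_any_day=True`` for sensitivity
    analyses.

    Returns one row per subject: subject_id, nine 0/1 ``ind_*`` columns,
    ``dds`` and ``tertile``.
    """
    if day != 1 and not allow_any_day:
        raise ValueError(
            "DDS is defined on recall day 1; pass allow_any_day=True to override"
        )
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    groups = SCHEMES[scheme]
    gcols = group_columns(scheme)
    missing = [c for c in gcols if c not in recalls.columns]
    if missing:
        raise ValidationError(f"recalls lack diversity-group columns {missing}")
    sel = recalls[recalls["recall_index"] == day]
    out = pd.DataFrame({"subject_id": sel["subject_id"].to_numpy()})
    total = np.zeros(len(sel), dtype=int)
    for g, c in zip(groups, gcols):
        ind = (sel[c].to_numpy(dtype=float) >= threshold).astype(int)
        out[f"ind_{g}"] = ind
        total += ind
    out["dds"] = total
    out["tertile"] = np.select([total <= 4, total == 5], [1, 2], default=3)
    return out


def group_frequencies(
    results: pd.DataFrame,
    scheme: str = "hdds9",
    by_tertile: bool = False,
) -> pd.DataFrame:
    """Share of subjects (percent) consuming each group, optionally per tertile.

    An empty tertile yields a row of empty frequencies rather than an error.
    """
    if results.empty:
        raise ValidationError("no DDS results to summarize")
    groups = SCHEMES[scheme]
    blocks: list[tuple[str | int, pd.DataFrame]] = (
        [(t, results[results["tertile"] == t]) for t in (1, 2, 3)]
        if by_tertile
        else [("all", results)]
    )
    rows = []
    for label, block in blocks:
        row: dict = {"tertile": label, "n": len(block)}
        for g in groups:
            row[g] = (
                100.0 * float(block[f"ind_{g}"].mean()) if len(block) else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
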