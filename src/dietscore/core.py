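"""Domain types, the 17-factor set, diversity-group schemes, and CSV I/O.

The pipeline scores two diet indices from repeated 24-h recalls:

* a quintile-based Diet Quality Score (DQS) over 17 dietary factors --
  10 scored as healthy (more is better) and 7 as unhealthy (less is better);
* a 9-food-group Diet Diversity Score (DDS) from the first recall day.

Subjects belong to one of 64 subgroups (8 countries x 2 sexes x 4 age bands);
quintile cut-points for the DQS are formed within those subgroups.

All interchange is plain CSV: comma separator, header row, "." decimal mark,
UTF-8.  Missing values are permitted only for anthropometry; a missing intake
value is an error because the scoring rules have no missingness convention.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

COUNTRIES: tuple[str, ...] = (
    "Argentina", "Brazil", "Chile", "Colombia",
    "Costa Rica", "Ecuador", "Peru", "Venezuela",
)
SEXES: tuple[str, ...] = ("male", "female")
AGE_GROUPS: tuple[str, ...] = ("15-19", "20-34", "35-49", "50-65")
SELS: tuple[str, ...] = ("high", "middle", "low")

#: (low, high) inclusive edges of each age band.
AGE_BAND_EDGES: dict[str, tuple[int, int]] = {
    "15-19": (15, 19),
    "20-34": (20, 34),
    "35-49": (35, 49),
    "50-65": (50, 65),
}


class ParseError(ValueError):
    """A value in an input file is outside its closed vocabulary or malformed."""


class ValidationError(ValueError):
    """Structurally parseable input violates a domain invariant."""


class SchemaError(ValueError):
    """An input file is missing required columns."""


def age_group_of(age_years: int) -> str:
    """Return the age band containing ``age_years`` (bands closed on both ends)."""
    for band, (lo, hi) in AGE_BAND_EDGES.items():
        if lo <= age_years <= hi:
            return band
    raise ValidationError(f"age {age_years} outside the study range [15, 65]")


@dataclass(frozen=True)
class FactorDef:
    """One of the 17 dietary factors entering the Diet Quality Score.

    ``direction`` decides how quintile rank maps to the item score: for a
    healthy factor the top quintile scores 5, for an unhealthy factor the
    bottom quintile scores 5.  ``unit`` is the factor's native unit; g/d and
    mg/d amounts are energy-adjusted to a 2000 kcal/day basis, % energy
    amounts are already energy-normalized.  ``episodic`` marks foods not
    consumed every day (zero-inflated recall values).
    """

    name: str
    direction: str  # "healthy" | "unhealthy"
    unit: str  # "g/d" | "mg/d" | "%energy"
    episodic: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("healthy", "unhealthy"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.unit not in ("g/d", "mg/d", "%energy"):
            raise ValueError(f"bad unit {self.unit!r}")


#: The default factor set: 10 healthy and 7 unhealthy items.
DEFAULT_FACTORS: tuple[FactorDef, ...] = (
    FactorDef("fruits", "healthy", "g/d"),
    FactorDef("vegetables", "healthy", "g/d"),
    FactorDef("beans_legumes", "healthy", "g/d"),
    FactorDef("nuts_seeds", "healthy", "g/d", episodic=True),
    FactorDef("whole_grains", "healthy", "g/d", episodic=True),
    FactorDef("milk", "healthy", "g/d"),
    FactorDef("polyunsaturated_fat_pct", "healthy", "%energy"),
    FactorDef("fish", "healthy", "g/d", episodic=True),
    FactorDef("plant_omega3", "healthy", "g/d"),
    FactorDef("dietary_fiber", "healthy", "g/d"),
    FactorDef("unprocessed_red_meats", "unhealthy", "g/d"),
    FactorDef("processed_meats", "unhealthy", "g/d"),
    FactorDef("sugar_sweetened_beverages", "unhealthy", "g/d"),
    FactorDef("saturated_fat_pct", "unhealthy", "%energy"),
    FactorDef("trans_fat_pct", "unhealthy", "%energy"),
    FactorDef("cholesterol", "unhealthy", "mg/d"),
    FactorDef("sodium", "unhealthy", "g/d"),
)

FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in DEFAULT_FACTORS)
HEALTHY_FACTOR_NAMES: tuple[str, ...] = tuple(
    f.name for f in DEFAULT_FACTORS if f.direction == "healthy"
)
UNHEALTHY_FACTOR_NAMES: tuple[str, ...] = tuple(
    f.name for f in DEFAULT_FACTORS if f.direction == "unhealthy"
)

# Nine-food-group schemes for the Diet Diversity Score.  HDDS-9 is the
# household-style grouping; WDDS-9 is the women's-diversity project grouping.
HDDS9_GROUPS: tuple[str, ...] = (
    "cereals", "white_roots_tubers", "vegetables", "fruits",
    "meat_poultry_offal", "fish_seafood", "eggs",
    "pulses_legumes_nuts", "milk_products",
)
WDDS9_GROUPS: tuple[str, ...] = (
    "starchy_staples", "dark_green_leafy_vegetables",
    "vitamin_a_fruits_vegetables", "other_fruits_vegetables",
    "organ_meat", "meat_fish", "eggs", "legumes_nuts_seeds", "milk_products",
)
SCHEMES: dict[str, tuple[str, ...]] = {"hdds9": HDDS9_GROUPS, "wdds9": WDDS9_GROUPS}


def group_columns(scheme: str) -> list[str]:
    """CSV column names carrying the grams of each diversity group."""
    try:
        groups = SCHEMES[scheme]
    except KeyError:
        raise ValueError(f"unknown diversity scheme {scheme!r}") from None
    return [f"grp_{g}" for g in groups]


class SubgroupKey(NamedTuple):
    """The (country, sex, age band) stratum within which quintiles are cut."""

    country: str
    sex: str
    age_group: str


def all_subgroup_keys() -> list[SubgroupKey]:
    return [
        SubgroupKey(c, s, a) for c in COUNTRIES for s in SEXES for a in AGE_GROUPS
    ]


@dataclass
class Subject:
    subject_id: str
    country: str
    sex: str
    age_years: int
    sel: str
    weight_kg: float | None = None
    height_cm: float | None = None
    wc_cm: float | None = None
    neck_cm: float | None = None
    bmi_for_age_flag: str | None = None

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_years)

    @property
    def subgroup(self) -> SubgroupKey:
        return SubgroupKey(self.country, self.sex, self.age_group)


@dataclass
class RecallDay:
    """One subject-day of intake: energy, the 17 factor amounts, 9 group grams."""

    subject_id: str
    recall_index: int
    day_type: str  # "weekday" | "weekend"
    energy_kcal: float
    factor_amounts: dict[str, float] = field(default_factory=dict)
    group_grams: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Knobs shared across stages; defaults reproduce the published protocol."""

    factors: tuple[FactorDef, ...] = DEFAULT_FACTORS
    scheme: str = "wdds9"
    dds_threshold_g: float = 15.0
    dds_day: int = 1
    quintile_tie_break: str = "subject_id"  # or "random"
    min_subgroup_size: int = 5
    shrink: bool = True
    transform: str = "log"  # or "none"
    bias_correction: bool = False
    two_part: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dds_threshold_g <= 0:
            raise ValueError("DDS gram threshold must be positive")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown diversity scheme {self.scheme!r}")


# ---------------------------------------------------------------------------
# Readers / writers

SUBJECT_COLUMNS = (
    "subject_id", "country", "sex", "age_years", "sel",
    "weight_kg", "height_cm", "wc_cm", "neck_cm",
)


def _opt_float(value, what: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    x = float(value)
    if x <= 0:
        raise ValidationError(f"row {row}: {what} must be strictly positive, got {x}")
    return x


def load_subjects(path: str | Path) -> pd.DataFrame:
    """Read and validate a subjects CSV into a DataFrame (one row per subject)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing subject columns {missing}")
    if "bmi_for_age_flag" not in df.columns:
        df["bmi_for_age_flag"] = pd.NA
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.country not in COUNTRIES:
            raise ParseError(f"{path} row {i}: unknown country {row.country!r}")
        if row.sex not in SEXES:
            raise ParseError(f"{path} row {i}: unknown sex {row.sex!r}")
        if row.sel not in SELS:
            raise ParseError(f"{path} row {i}: unknown socio-economic level {row.sel!r}")
        age = int(row.age_years)
        if not 15 <= age <= 65:
            raise ValidationError(f"{path} row {i}: age {age} outside [15, 65]")
        for col in ("weight_kg", "height_cm", "wc_cm", "neck_cm"):
            _opt_float(getattr(row, col), col, i)
    df["age_years"] = df["age_years"].astype(int)
    df["age_group"] = [age_group_of(a) for a in df["age_years"]]
    return df


def read_subjects(path: str | Path) -> list[Subject]:
    """Read a subjects CSV as a list of :class:`Subject`."""
    df = load_subjects(path)
    out: list[Subject] = []
    for row in df.itertuples(index=False):
        flag = row.bmi_for_age_flag
        if pd.isna(flag):
            flag = None
        out.append(
            Subject(
                subject_id=row.subject_id,
                country=row.country,
                sex=row.sex,
                age_years=int(row.age_years),
                sel=row.sel,
                weight_kg=None if pd.isna(row.weight_kg) else float(row.weight_kg),
                height_cm=None if pd.isna(row.height_cm) else float(row.height_cm),
                wc_cm=None if pd.isna(row.wc_cm) else float(row.wc_cm),
                neck_cm=None if pd.isna(row.neck_cm) else float(row.neck_cm),
                bmi_for_age_flag=flag,
            )
        )
    return out


def load_recalls(
    path: str | Path,
    factors: Sequence[FactorDef] = DEFAULT_FACTORS,
    scheme: str = "wdds9",
) -> pd.DataFrame:
    """Read and validate a recalls CSV (one row per subject-day)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    fcols = [f.name for f in factors]
    gcols = group_columns(scheme)
    required = ["subject_id", "recall_index", "day_type", "energy_kcal"] + fcols + gcols
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing recall columns {missing}")
    if df[["subject_id", "recall_index"]].duplicated().any():
        bad = df.loc[df[["subject_id", "recall_index"]].duplicated()].iloc[0]
        raise ValidationError(
            f"{path}: duplicate recall (subject {bad['subject_id']!r}, "
            f"index {bad['recall_index']})"
        )
    if not df["recall_index"].isin((1, 2)).all():
        raise ValidationError(f"{path}: recall_index must be 1 or 2")
    if not df["day_type"].isin(("weekday", "weekend")).all():
        raise ParseError(f"{path}: day_type must be weekday or weekend")
    amounts = df[["energy_kcal"] + fcols + gcols]
    if amounts.isna().any().any():
        col = amounts.columns[amounts.isna().any()][0]
        raise ValidationError(f"{path}: missing intake value in column {col!r}")
    if (df["energy_kcal"] <= 0).any():
        raise ValidationError(f"{path}: energy_kcal must be positive")
    neg = amounts.lt(0).any()
    if neg.any():
        raise ValidationError(
            f"{path}: negative amount in column {neg.index[neg][0]!r}"
        )
    df["recall_index"] = df["recall_index"].astype(int)
    return df


def read_recalls(
    path: str | Path,
    factors: Sequence[FactorDef] = DEFAULT_FACTORS,
    scheme: str = "wdds9",
) -> list[RecallDay]:
    """Read a recalls CSV as a list of :class:`RecallDay`."""
    df = load_recalls(path, factors, scheme)
    fcols = [f.name for f in factors]
    groups = SCHEMES[scheme]
    gcols = group_columns(scheme)
    out: list[RecallDay] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            RecallDay(
                subject_id=d["subject_id"],
                recall_index=int(d["recall_index"]),
                day_type=d["day_type"],
                energy_kcal=float(d["energy_kcal"]),
                factor_amounts={c: float(d[c]) for c in fcols},
                group_grams={g: float(d[c]) for g, c in zip(groups, gcols)},
            )
        )
    return out


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (197.195 -> 197.20 at 2 digits)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _format_cell(value, precision: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        q = decimal.Decimal(1).scaleb(-precision)
        return str(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))
    return str(value)


def write_table(
    rows: pd.DataFrame | Iterable[Mapping],
    path: str | Path,
    precision: int = 2,
) -> None:
    """Write summary rows as deterministic CSV.

    Column order follows the input; floats are rendered with ``precision``
    decimals using round-half-up; re-running on identical input produces a
    byte-identical file.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    path = Path(path)
    lines = [",".join(map(str, rows.columns))]
    for row in rows.itertuples(index=False):
        lines.append(",".join(_format_cell(v, precision) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_data(df: pd.DataFrame, path: str | Path) -> None:
    """Write a data table at full precision (round-trip exact)."""
    df.to_csv(path, index=False)
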