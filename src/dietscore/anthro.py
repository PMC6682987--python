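"""Anthropometric classification for stratified reporting.

Adult BMI bands follow the WHO convention as used in the survey protocol,
taken literally even where asymmetric: underweight is BMI <= 18.5 (boundary
inclusive), normal (18.5, 25.0), overweight [25.0, 30.0), obese >= 30.0.
Under-18 subjects are classified by a precomputed BMI-for-age category
supplied with the input data (WHO 2007 reference tables are not
reimplemented); an adolescent without one is reported as "unclassifiable".

Waist circumference risk cut-offs are >= 102 cm (men) / >= 88 cm (women).
Neck circumference cut-offs are strict: > 39 cm (adult men) / > 35 cm (adult
women), and > 34.25 / > 31.5 cm for adolescents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BMI_CLASSES = ("underweight", "normal", "overweight", "obese")


def bmi_value(weight_kg: float, height_cm: float) -> float:
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return weight_kg / (height_cm / 100.0) ** 2


def classify_bmi(
    weight_kg: float,
    height_cm: float,
    age_years: int,
    precomputed_flag: str | None = None,
) -> str:
    """BMI class: adult bands for age >= 18, precomputed category otherwise."""
    if age_years < 18:
        return precomputed_flag if precomputed_flag else "unclassifiable"
    bmi = bmi_value(weight_kg, height_cm)
    if bmi <= 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def classify_wc(wc_cm: float, sex: str) -> str:
    """"above" iff waist circumference reaches the sex-specific cut-off."""
    if wc_cm <= 0:
        raise ValueError("waist circumference must be positive")
    cut = 102.0 if sex == "male" else 88.0
    return "above" if wc_cm >= cut else "below"


def classify_neck(neck_cm: float, sex: str, age_years: int) -> str:
    """"above" iff neck circumference strictly exceeds the age/sex cut-off."""
    if neck_cm <= 0:
        raise ValueError("neck circumference must be positive")
    if age_years < 18:
        cut = 34.25 if sex == "male" else 31.5
    else:
        cut = 39.0 if sex == "male" else 35.0
    return "above" if neck_cm > cut else "below"


def classify_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Classify every subject; missing measurements yield empty classes."""
    rows = []
    for s in subjects.itertuples(index=False):
        weight = getattr(s, "weight_kg", None)
        height = getattr(s, "height_cm", None)
        row: dict = {"subject_id": s.subject_id}
        if pd.notna(weight) and pd.notna(height):
            row["bmi"] = bmi_value(float(weight), float(height))
            flag = getattr(s, "bmi_for_age_flag", None)
            if pd.isna(flag) or flag == "":
                flag = None
            row["bmi_class"] = classify_bmi(
                float(weight), float(height), int(s.age_years), flag
            )
        else:
            row["bmi"] = np.nan
            row["bmi_class"] = ""
        wc = getattr(s, "wc_cm", None)
        row["wc_class"] = classify_wc(float(wc), s.sex) if pd.notna(wc) else ""
        neck = getattr(s, "neck_cm", None)
        row["neck_class"] = (
            classify_neck(float(neck), s.sex, int(s.age_years))
            if pd.notna(neck)
            else ""
        )
        rows.append(row)
    return pd.DataFrame(rows)
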